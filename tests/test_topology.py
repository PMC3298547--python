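"""Pairwise disconnectivity, bow-tie structure, fold-change, Levene."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import levene as scipy_levene

from priornet.netcore import DirectedNetwork, remove_orphans
from priornet.filtering import ExpressionSet, IdentifierMap
from priornet.topology import (
    dis_index,
    dis_increase,
    bowtie_decompose,
    log_fold_change,
    levene_test,
    compartment_variance_report,
)

from conftest import random_network


def oracle_dis(net, convention="mediator"):
    """Exhaustive remove-and-recount oracle via networkx BFS reachability."""
    g = net.as_digraph()

    def pairs(h):
        return {
            (s, t) for s in h for t in nx.descendants(h, s) if t != s
        }

    base = pairs(g)
    out = {}
    for v in sorted(net.vertices):
        n0 = len([p for p in base if v not in p]) if convention == "mediator" \
            else len(base)
        h = g.copy()
        h.remove_node(v)
        n_minus = len(pairs(h))
        out[v] = (n0, n_minus, (n0 - n_minus) / n0 if n0 else 0.0)
    return out


class TestDisIndex:
    def test_path_interior_vertex_scores_one(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        ds = dis_index(net)
        assert ds.value("b") == 1.0
        assert ds.value("a") == 0.0 and ds.value("c") == 0.0
        assert ds.normalized_value("b") == 1.0

    def test_complete_digraph_all_zero(self):
        edges = [(a, b) for a in "abc" for b in "abc" if a != b]
        ds = dis_index(DirectedNetwork.from_edges(edges))
        assert np.all(ds.dis == 0.0)
        assert np.all(ds.normalized == 0.0)

    def test_leaf_without_throughput_scores_zero(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("a", "c")])
        assert dis_index(net).value("c") == 0.0

    def test_too_small_network_rejected(self):
        net = DirectedNetwork.from_edges([], vertices=["a"])
        with pytest.raises(ValueError):
            dis_index(net)

    @pytest.mark.parametrize("convention", ["mediator", "all_pairs"])
    def test_matches_exhaustive_oracle(self, convention):
        rng = np.random.default_rng(55)
        for _ in range(25):
            net = remove_orphans(random_network(rng, n_max=25))
            if net.n_vertices < 2:
                continue
            ds = dis_index(net, pair_convention=convention)
            ora = oracle_dis(net, convention)
            for i, v in enumerate(ds.order):
                n0, n_minus, dis = ora[v]
                assert ds.n0[i] == n0
                assert ds.n_minus[i] == n_minus
                assert ds.dis[i] == pytest.approx(dis, abs=1e-12)

    def test_removal_never_creates_pairs(self):
        rng = np.random.default_rng(56)
        for _ in range(20):
            net = remove_orphans(random_network(rng, n_max=25))
            if net.n_vertices < 2:
                continue
            ds = dis_index(net)
            assert np.all(ds.n_minus <= ds.n0)
            assert np.all(ds.dis >= 0.0)


class TestDisIncrease:
    def test_identity_networks_give_zero(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        ds = dis_index(net)
        comp = dis_increase(ds, ds)
        assert np.allclose(comp.delta, 0.0)

    def test_bound_attained(self):
        # b mediates in the filtered path; in the reference a shortcut
        # makes d the sole bottleneck and b inert
        filtered = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        reference = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")]
        )
        comp = dis_increase(dis_index(filtered), dis_index(reference))
        assert comp.value("b") == pytest.approx(1.0)

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(58)
        done = 0
        while done < 10:
            a = remove_orphans(random_network(rng, n_max=20))
            if a.n_vertices < 3:
                continue
            vs = sorted(a.vertices)
            keep = {v for v in vs if rng.random() < 0.7} | set(vs[:3])
            b = remove_orphans(a.induced_subgraph(keep))
            if b.n_vertices < 2:
                continue
            da, db = dis_index(a), dis_index(b)
            if da.dis.max() == 0 or db.dis.max() == 0:
                continue
            ab = dis_increase(db, da)  # b's vertices are in a
            assert np.all(np.abs(ab.delta) <= 1.0 + 1e-12)
            shared = [v for v in db.order]
            ba = {
                v: da.normalized_value(v) - db.normalized_value(v) for v in shared
            }
            for v in shared:
                assert ab.value(v) == pytest.approx(-ba[v], abs=1e-12)
            done += 1

    def test_zero_max_rejected(self):
        flat = DirectedNetwork.from_edges([("a", "b"), ("c", "d")])
        ds = dis_index(flat)
        assert ds.dis.max() == 0.0
        with pytest.raises(ValueError):
            dis_increase(ds, ds)


class TestBowtie:
    def test_hand_derived_example(self):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "a"), ("d", "a"), ("b", "c")]
        )
        bt = bowtie_decompose(net)
        assert bt.lscc == {"a", "b"}
        assert bt.labels == {"a": "LSCC", "b": "LSCC", "d": "IN", "c": "OUT"}

    def test_single_cycle_is_all_lscc(self):
        bt = bowtie_decompose(
            DirectedNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        )
        assert bt.sizes == {"LSCC": 3, "IN": 0, "OUT": 0, "OTHER": 0}

    def test_tie_broken_lexicographically(self):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "a"), ("x", "y"), ("y", "x")]
        )
        assert bowtie_decompose(net).lscc == {"a", "b"}

    def test_degenerate_flagged(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        bt = bowtie_decompose(net)
        assert bt.degenerate
        assert set(bt.labels.values()) == {"OTHER"}

    def test_labels_invariant_under_relabeling(self):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "a"), ("d", "a"), ("b", "c")]
        )
        ren = {"a": "q", "b": "r", "c": "s", "d": "t"}
        net2 = DirectedNetwork.from_edges(
            [(ren[u], ren[v]) for u, v in net.edges()]
        )
        bt1, bt2 = bowtie_decompose(net), bowtie_decompose(net2)
        assert {ren[v]: lab for v, lab in bt1.labels.items()} == bt2.labels

    def test_compartments_verified_by_reachability_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(25):
            net = random_network(rng, n_max=30)
            bt = bowtie_decompose(net)
            if bt.degenerate:
                continue
            g = net.as_digraph()
            rep = min(bt.lscc)
            for v, lab in bt.labels.items():
                reaches = v in bt.lscc or nx.has_path(g, v, rep)
                reached = v in bt.lscc or nx.has_path(g, rep, v)
                if lab == "IN":
                    assert reaches and not reached
                elif lab == "OUT":
                    assert reached and not reaches
                elif lab == "LSCC":
                    assert v in bt.lscc


class TestLogFoldChange:
    def _idmap(self):
        return IdentifierMap([("t_a", "a"), ("t_b1", "b"), ("t_b2", "b")])

    def test_equal_normalized_abundance_zero(self):
        idmap = self._idmap()
        n = ExpressionSet("n", {"t_a": 10, "t_b1": 10})
        d = ExpressionSet("d", {"t_a": 10, "t_b1": 10})
        de = log_fold_change(n, d, idmap)
        assert de.values["a"] == 0.0

    def test_absent_in_normal_finite_positive(self):
        idmap = self._idmap()
        n = ExpressionSet("n", {"t_a": 10})
        d = ExpressionSet("d", {"t_a": 10, "t_b1": 5})
        de = log_fold_change(n, d, idmap)
        assert math.isfinite(de.values["b"]) and de.values["b"] > 0

    def test_library_size_invariance(self):
        idmap = self._idmap()
        n = ExpressionSet("n", {"t_a": 10, "t_b1": 30})
        d1 = ExpressionSet("d", {"t_a": 10, "t_b1": 30})
        d2 = ExpressionSet("d", {"t_a": 20, "t_b1": 60})
        de1 = log_fold_change(n, d1, idmap)
        de2 = log_fold_change(n, d2, idmap)
        assert np.allclose(de1.values, de2.values)

    def test_tags_aggregated_per_vertex(self):
        # b's two tags in normal sum to the same abundance as its one
        # tag in disease, so the aggregated ratio is (nearly) zero
        idmap = self._idmap()
        n = ExpressionSet("n", {"t_a": 10, "t_b1": 5, "t_b2": 5})
        d = ExpressionSet("d", {"t_a": 10, "t_b1": 10})
        de = log_fold_change(n, d, idmap)
        assert de.values["b"] == pytest.approx(0.0, abs=1e-6)

    def test_direction_flips_sign(self):
        idmap = self._idmap()
        n = ExpressionSet("n", {"t_a": 5})
        d = ExpressionSet("d", {"t_a": 20})
        fwd = log_fold_change(n, d, idmap)
        rev = log_fold_change(n, d, idmap, direction="normal_vs_disease")
        assert fwd.values["a"] == pytest.approx(-rev.values["a"])


class TestLevene:
    def test_worked_two_group_example(self):
        res = levene_test([[0, 1, 2], [0, 2, 4]])
        assert res.W == pytest.approx(0.8)

    def test_identical_groups(self):
        res = levene_test([[1.0, 2.0], [1.0, 2.0]])
        assert res.W == 0.0 and res.p == 1.0

    def test_degenerate_flagged(self):
        # constant |deviations| within groups but different between them
        res = levene_test([[0.0, 2.0], [0.0, 4.0]])
        assert res.degenerate

    def test_matches_scipy_mean_centered(self):
        rng = np.random.default_rng(91)
        for _ in range(20):
            groups = [rng.normal(size=int(rng.integers(5, 30))) for _ in range(3)]
            res = levene_test(groups)
            w_ref, p_ref = scipy_levene(*groups, center="mean")
            assert res.W == pytest.approx(w_ref, rel=1e-10)
            assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            levene_test([[1, 2]])
        with pytest.raises(ValueError):
            levene_test([[1], [2, 3]])


class TestCompartmentVariance:
    def test_constant_lfc_degenerate_flag(self):
        import pandas as pd
        from priornet.topology import BowTie, DiffExpression

        bt = BowTie(labels={"a": "LSCC", "b": "LSCC", "c": "IN", "d": "IN"})
        de = DiffExpression(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}),
                            "d", "n", 0.5)
        table, lev = compartment_variance_report(bt, de)
        assert lev.W == 0.0 and lev.p == 1.0

    def test_table_rows_match_eligible_compartments(self):
        import pandas as pd
        from priornet.topology import BowTie, DiffExpression

        bt = BowTie(labels={"a": "LSCC", "b": "LSCC", "c": "IN", "d": "IN",
                            "e": "OUT"})
        de = DiffExpression(
            pd.Series({"a": 0.1, "b": -0.2, "c": 1.4, "d": -1.0, "e": 0.3}),
            "d", "n", 0.5,
        )
        table, _ = compartment_variance_report(bt, de)
        assert list(table["compartment"]) == ["LSCC", "IN"]  # OUT has n=1

    def test_too_few_compartments_rejected(self):
        import pandas as pd
        from priornet.topology import BowTie, DiffExpression

        bt = BowTie(labels={"a": "LSCC", "b": "LSCC"})
        de = DiffExpression(pd.Series({"a": 0.1, "b": 0.2}), "d", "n", 0.5)
        with pytest.raises(ValueError):
            compartment_variance_report(bt, de)
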