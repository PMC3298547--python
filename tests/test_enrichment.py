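"""Expression weights, noncentral Fisher tests, MC p-values, q-values."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, hypergeom, nchypergeom_fisher

from priornet.netcore import DirectedNetwork
from priornet.enrichment import (
    PathwayCollection,
    TissueExpressionMatrix,
    OverlapTable,
    compute_weights,
    group_odds,
    noncentral_hypergeom_pmf,
    noncentral_fisher_test,
    central_fisher_test,
    monte_carlo_extended_test,
    weighted_sample_without_replacement,
    storey_qvalues,
    enrich_all,
)


def exact_tail_oracle(N, K, n, k, omega_num, omega_den=1):
    """Enumerate all margin-preserving tables with exact rational arithmetic."""
    lo, hi = max(0, n - N + K), min(n, K)
    w = Fraction(omega_num, omega_den)
    weights = {x: comb(K, x) * comb(N - K, n - x) * w**x for x in range(lo, hi + 1)}
    total = sum(weights.values())
    tail = sum(v for x, v in weights.items() if x >= k)
    return Fraction(tail, total)


def make_tm(rows: dict, spot_map=None):
    df = pd.DataFrame.from_dict(rows, orient="index")
    return TissueExpressionMatrix(df, spot_map or {s: {s} for s in rows})


class TestWeights:
    def test_row_sum_proportions(self):
        tm = make_tm({"a": [1, 2], "b": [1, 0]})
        w = compute_weights(tm, {"a", "b"})
        assert np.allclose(w.p, [0.75, 0.25])

    def test_multiple_spots_summed(self):
        tm = make_tm(
            {"s1": [1, 1], "s2": [2, 0]}, spot_map={"s1": {"a"}, "s2": {"a"}}
        )
        w = compute_weights(tm, {"a"})
        assert w.weight("a") == 4

    def test_identical_rows_uniform(self):
        tm = make_tm({c: [2, 3] for c in "abcd"})
        w = compute_weights(tm, set("abcd"))
        assert np.allclose(w.p, 0.25)

    def test_spotless_vertex_excluded_and_reported(self):
        tm = make_tm({"a": [1]})
        w = compute_weights(tm, {"a", "ghost"})
        assert w.excluded == ["ghost"]
        assert w.order == ["a"]

    def test_zero_rows_imputed_smallest_positive(self):
        tm = make_tm({"a": [4.0], "b": [0.0]})
        w = compute_weights(tm, {"a", "b"})
        assert w.weight("b") == 4.0  # smallest positive
        assert w.n_zero_imputed == 1

    def test_all_zero_matrix_rejected(self):
        tm = make_tm({"a": [0.0], "b": [0.0]})
        with pytest.raises(ValueError, match="zero"):
            compute_weights(tm, {"a", "b"})


class TestGroupOdds:
    def test_equal_weights_unit_odds(self):
        tm = make_tm({c: [1.0] for c in "abcd"})
        w = compute_weights(tm, set("abcd"))
        assert group_odds(w, {"a", "b"}) == pytest.approx(1.0)

    def test_mean_ratio_and_scale_invariance(self):
        for scale in (1.0, 17.5):
            tm = make_tm({"a": [4.0 * scale], "b": [2.0 * scale], "c": [2.0 * scale]})
            w = compute_weights(tm, {"a", "b", "c"})
            assert group_odds(w, {"a"}) == pytest.approx(2.0)

    def test_degenerate_groups_rejected(self):
        tm = make_tm({"a": [1.0], "b": [1.0]})
        w = compute_weights(tm, {"a", "b"})
        with pytest.raises(ValueError):
            group_odds(w, set())
        with pytest.raises(ValueError):
            group_odds(w, {"a", "b"})


class TestNoncentralFisher:
    @pytest.mark.parametrize(
        "N,K,n,k,omega,expected",
        [
            (10, 5, 4, 4, 1.0, Fraction(5, 210)),
            (4, 2, 2, 2, 1.0, Fraction(1, 6)),
            (4, 2, 2, 2, 2.0, Fraction(4, 13)),
        ],
    )
    def test_hand_derived_examples(self, N, K, n, k, omega, expected):
        t = OverlapTable(N=N, K=K, n=n, k=k, omega=omega)
        assert noncentral_fisher_test(t) == pytest.approx(float(expected), abs=1e-14)

    def test_minimum_of_support_gives_p_one(self):
        t = OverlapTable(N=10, K=7, n=6, k=3, omega=2.5)  # k at support minimum
        assert noncentral_fisher_test(t) == 1.0

    def test_k_outside_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            OverlapTable(N=10, K=5, n=4, k=5, omega=1.0)

    def test_pmf_matches_scipy_and_sums_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            N = int(rng.integers(2, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            omega = float(rng.choice([0.1, 0.5, 1.0, 2.0, 10.0]))
            x, pmf = noncentral_hypergeom_pmf(N, K, n, omega)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
            ref = nchypergeom_fisher.pmf(x, N, K, n, omega)
            assert np.allclose(pmf, ref, atol=1e-10)

    def test_tail_monotone_in_k(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            N = int(rng.integers(4, 40))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            omega = float(rng.choice([0.25, 1.0, 4.0]))
            lo, hi = max(0, n - N + K), min(n, K)
            ps = [
                noncentral_fisher_test(OverlapTable(N=N, K=K, n=n, k=k, omega=omega))
                for k in range(lo, hi + 1)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_central_equals_scipy_fisher(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            N = int(rng.integers(2, 50))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n - N + K), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            t = OverlapTable(N=N, K=K, n=n, k=k, omega=1.0)
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            _, p_ref = fisher_exact(table, alternative="greater")
            assert central_fisher_test(t) == pytest.approx(p_ref, abs=1e-12)

    def test_matches_rational_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            N = int(rng.integers(2, 20))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo, hi = max(0, n - N + K), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            num, den = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = noncentral_fisher_test(
                OverlapTable(N=N, K=K, n=n, k=k, omega=num / den)
            )
            assert p == pytest.approx(float(exact_tail_oracle(N, K, n, k, num, den)),
                                      abs=1e-12)


class TestWeightedSampling:
    def test_shapes_and_distinctness(self):
        rng = np.random.default_rng(1)
        sel = weighted_sample_without_replacement(np.ones(10), 4, rng, n_draws=50)
        assert sel.shape == (50, 4)
        assert all(len(set(row)) == 4 for row in sel)

    def test_inclusion_tracks_weights(self):
        rng = np.random.default_rng(2)
        w = np.array([10.0, 1.0, 1.0, 1.0, 1.0])
        sel = weighted_sample_without_replacement(w, 2, rng, n_draws=4000)
        freq0 = (sel == 0).any(axis=1).mean()
        freq1 = (sel == 1).any(axis=1).mean()
        assert freq0 > 0.9  # heavy item almost always drawn
        assert 0.15 < freq1 < 0.35

    def test_full_sample_returns_everything(self):
        rng = np.random.default_rng(3)
        sel = weighted_sample_without_replacement(np.ones(5), 5, rng, n_draws=2)
        assert set(sel[0]) == set(range(5))


class TestMonteCarlo:
    def _setup(self):
        net = DirectedNetwork.from_edges([], vertices=[f"v{i}" for i in range(20)])
        tm = make_tm({f"v{i}": [1.0] for i in range(20)})
        w = compute_weights(tm, net.vertices)
        return net, w

    def test_zero_observed_overlap_gives_p_one(self):
        net, w = self._setup()
        p, _ = monte_carlo_extended_test(
            net, w, 5, {"v0", "v1"}, observed_overlap=0, T=200, seed=1
        )
        assert p == 1.0

    def test_same_seed_reproducible(self):
        net, w = self._setup()
        r1 = monte_carlo_extended_test(net, w, 5, {"v0", "v1", "v2"}, 2, T=500, seed=9)
        r2 = monte_carlo_extended_test(net, w, 5, {"v0", "v1", "v2"}, 2, T=500, seed=9)
        assert r1[0] == r2[0]
        assert np.array_equal(r1[1], r2[1])

    def test_empirical_p_in_valid_range(self):
        net, w = self._setup()
        p, _ = monte_carlo_extended_test(
            net, w, 5, set(net.vertices), observed_overlap=5, T=100, seed=0
        )
        assert 1 / 101 <= p <= 1.0

    def test_invalid_arguments_rejected(self):
        net, w = self._setup()
        with pytest.raises(ValueError):
            monte_carlo_extended_test(net, w, 5, {"v0"}, 1, T=0, seed=0)
        with pytest.raises(ValueError):
            monte_carlo_extended_test(net, w, 50, {"v0"}, 1, T=10, seed=0)


class TestStoreyQvalues:
    def test_bh_reduction_worked_example(self):
        q = storey_qvalues([0.01, 0.02, 0.03], lam=0.0)
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(storey_qvalues([1.0, 1.0, 1.0], lam=0.5), 1.0)

    def test_single_p(self):
        q = storey_qvalues([0.2], lam=0.0)
        assert q[0] == pytest.approx(0.2)

    def test_empty_input(self):
        assert storey_qvalues([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.0, 0.5])

    def test_monotone_permutation_invariant_bounded(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 60)))
            q = storey_qvalues(p, lam=0.5)
            assert np.all(q <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p
            perm = rng.permutation(p.size)
            assert np.allclose(storey_qvalues(p[perm], lam=0.5), q[perm])
            m = p.size
            pi0 = min(1.0, max((p > 0.5).sum() / (m * 0.5), 1 / m))
            assert np.all(q >= np.minimum(1.0, pi0 * p) - 1e-12)

    def test_ties_share_q(self):
        q = storey_qvalues([0.02, 0.02, 0.5], lam=0.0)
        assert q[0] == q[1]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                 max_size=40),
        st.floats(min_value=0.0, max_value=0.9),
    )
    def test_qvalues_sound_for_arbitrary_inputs(self, pvals, lam):
        q = storey_qvalues(pvals, lam=lam)
        assert np.all((0 < q) & (q <= 1.0))
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestEnrichAll:
    def _fixture(self):
        net = DirectedNetwork.from_edges(
            [(f"v{i}", f"v{i+1}") for i in range(9)]
        )
        tm = make_tm({f"v{i}": [1.0 + 0.1 * i] for i in range(10)})
        w = compute_weights(tm, net.vertices)
        pw = PathwayCollection(
            {"big": {"v0", "v1", "v2", "v3"}, "tiny": {"v9"}, "off": {"v8", "v9"}}
        )
        return net, w, pw

    def test_min_overlap_excludes_from_family(self):
        net, w, pw = self._fixture()
        res = enrich_all(net, {"v0", "v1", "v2", "v9"}, pw, w, mode="strict_exact")
        assert set(res["pathway"]) == {"big"}  # tiny/off overlap < 2

    def test_single_tested_pathway_q_formula(self):
        net, w, pw = self._fixture()
        res = enrich_all(
            net, {"v0", "v1", "v2", "v9"}, pw, w, mode="strict_exact", lam=0.0
        )
        assert len(res) == 1
        assert res.loc[0, "q"] == pytest.approx(min(1.0, res.loc[0, "p"]))

    def test_rows_sorted_by_q_then_p(self):
        net, w, pw = self._fixture()
        res = enrich_all(net, set(net.vertices), pw, w, mode="central", min_overlap=1)
        assert list(res["q"]) == sorted(res["q"])

    def test_central_mode_reports_unit_omega(self):
        net, w, pw = self._fixture()
        res = enrich_all(net, {"v0", "v1", "v2"}, pw, w, mode="central")
        assert (res["omega"] == 1.0).all()
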