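"""Key-node scoring, bow-tie decomposition and differential expression.

The pairwise disconnectivity index Dis(v) measures the fraction of
initially connected ordered vertex pairs that lose their connection
when v is removed - a non-local bottleneck score.  Counting connected
ordered pairs is done on the condensation of the graph: within a
strongly connected component of size s there are s*(s-1) ordered
pairs, and across components the transitive closure of the
condensation DAG gives the remaining ones.  The closure is recomputed
from scratch after each single-vertex removal; at the scale this
package targets (reference networks of a couple of thousand vertices)
that is a few tens of seconds, which we accept for the sake of an
exact, oracle-matchable count.

Bow-tie structure (LSCC / IN / OUT / OTHER) and the variance of
per-vertex differential expression across bow-tie compartments
(Levene's test) complete the picture: topologically central vertices
tend to be stably expressed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist

from priornet.netcore import DirectedNetwork
from priornet.filtering import ExpressionSet, IdentifierMap

__all__ = [
    "DisScores",
    "DisComparison",
    "BowTie",
    "DiffExpression",
    "LeveneResult",
    "dis_index",
    "dis_increase",
    "bowtie_decompose",
    "log_fold_change",
    "levene_test",
    "compartment_variance_report",
]

PAIR_CONVENTIONS = ("mediator", "all_pairs")


# ----------------------------------------------------------------------
# Connected ordered-pair counting via SCC condensation
# ----------------------------------------------------------------------


def _condensation_closure(adj: csr_array):
    """Sizes and reachability closure of the SCC condensation DAG."""
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    sz = np.bincount(labels, minlength=ncomp).astype(np.int64)
    coo = adj.tocoo()
    cu = labels[coo.row]
    cv = labels[coo.col]
    mask = cu != cv
    if mask.any():
        pairs = np.unique(np.stack([cu[mask], cv[mask]], axis=1), axis=0)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)

    succ: list[list[int]] = [[] for _ in range(ncomp)]
    indeg = np.zeros(ncomp, dtype=np.int64)
    for c, d in pairs:
        succ[c].append(d)
        indeg[d] += 1
    # Kahn topological order; iterate it reversed so successors are done first
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    topo: list[int] = []
    indeg = indeg.copy()
    while queue:
        c = queue.popleft()
        topo.append(c)
        for d in succ[c]:
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)

    reach = np.zeros((ncomp, ncomp), dtype=bool)
    for c in reversed(topo):
        row = reach[c]
        for d in succ[c]:
            row |= reach[d]
            row[d] = True
    return labels, sz, reach


def _pair_counts(adj: csr_array, per_vertex: bool = False):
    """Number of connected ordered pairs (s, t), s != t, with a path s->t.

    With ``per_vertex`` also returns, for every vertex, the number of
    connected pairs in which it is the source resp. the target.
    """
    labels, sz, reach = _condensation_closure(adj)
    reach_i = reach.astype(np.int64)
    w_out = reach_i @ sz  # downstream vertices per component (excl. own)
    total = int((sz * (sz - 1)).sum() + sz @ w_out)
    if not per_vertex:
        return total
    w_in = sz @ reach_i  # upstream vertices per component
    out_v = sz[labels] - 1 + w_out[labels]
    in_v = sz[labels] - 1 + w_in[labels]
    return total, out_v, in_v


@dataclass
class DisScores:
    """Pairwise disconnectivity per vertex of one network.

    ``n0`` is the per-vertex baseline count of connected ordered pairs
    (excluding pairs involving the vertex itself under the default
    mediator convention), ``n_minus`` the count after the vertex'
    removal.  ``normalized`` divides by the maximum score, filling
    (0, 1] with exactly 1 at the argmax whenever any score is positive.
    """

    order: list[str]
    dis: np.ndarray
    normalized: np.ndarray
    n0: np.ndarray
    n_minus: np.ndarray
    convention: str = "mediator"

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.order)}

    def value(self, vertex: str) -> float:
        return float(self.dis[self._index[vertex]])

    def normalized_value(self, vertex: str) -> float:
        return float(self.normalized[self._index[vertex]])

    def __contains__(self, vertex: str) -> bool:
        return vertex in self._index

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": self.order,
                "dis": self.dis,
                "dis_normalized": self.normalized,
                "n0": self.n0,
                "n_minus": self.n_minus,
            }
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def dis_index(
    net: DirectedNetwork, pair_convention: str = "mediator"
) -> DisScores:
    """Pairwise disconnectivity index for every vertex.

    For each vertex v, N0(v) counts the connected ordered pairs of the
    intact network and N-v those after removing v; Dis(v) is their
    relative loss (0 when N0(v) = 0).  Under the default ``mediator``
    convention pairs involving v itself are excluded from N0(v), so the
    score isolates v's role as an intermediary; ``all_pairs`` keeps
    them, so endpoints of destroyed pairs score too.

    Orphan vertices should be removed beforehand (their removal changes
    no connectivity and they would only dilute the normalization).
    """
    if pair_convention not in PAIR_CONVENTIONS:
        raise ValueError(
            f"unknown pair convention {pair_convention!r}; "
            f"expected one of {PAIR_CONVENTIONS}"
        )
    order = sorted(net.vertices)
    n = len(order)
    if n < 2:
        raise ValueError("dis_index needs at least 2 vertices")
    adj = nx.to_scipy_sparse_array(
        net.as_digraph(), nodelist=order, dtype=np.float32, format="csr"
    )
    total, out_v, in_v = _pair_counts(adj, per_vertex=True)
    if pair_convention == "mediator":
        n0 = total - out_v - in_v
    else:
        n0 = np.full(n, total, dtype=np.int64)

    n_minus = np.empty(n, dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        keep = np.delete(idx, i)
        sub = adj[keep][:, keep]
        n_minus[i] = _pair_counts(sub)

    with np.errstate(invalid="ignore", divide="ignore"):
        dis = np.where(n0 > 0, (n0 - n_minus) / np.maximum(n0, 1), 0.0)
    mx = dis.max() if n else 0.0
    normalized = dis / mx if mx > 0 else np.zeros_like(dis)
    return DisScores(
        order=order,
        dis=dis.astype(float),
        normalized=normalized,
        n0=n0,
        n_minus=n_minus,
        convention=pair_convention,
    )


@dataclass
class DisComparison:
    """Max-normalized Dis difference (filtered minus reference) per vertex."""

    order: list[str]
    delta: np.ndarray
    filtered_normalized: np.ndarray
    reference_normalized: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.order)}

    def value(self, vertex: str) -> float:
        return float(self.delta[self._index[vertex]])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": self.order,
                "delta_dis": self.delta,
                "dis_filtered_normalized": self.filtered_normalized,
                "dis_reference_normalized": self.reference_normalized,
            }
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def dis_increase(filtered: DisScores, reference: DisScores) -> DisComparison:
    """Dis-increase of every filtered vertex relative to the reference.

    Delta(v) = Dis_f(v)/max Dis_f - Dis_r(v)/max Dis_r, computed only
    for vertices of the filtered network; it quantifies how much
    influence a vertex gains (or loses) through the filtering.  Raises
    when either maximum is zero (normalization undefined).
    """
    missing = [v for v in filtered.order if v not in reference]
    if missing:
        raise KeyError(
            f"filtered vertices absent from reference scores: {missing[:5]}"
        )
    if filtered.dis.max() <= 0 or reference.dis.max() <= 0:
        raise ValueError("max Dis is zero; normalized comparison undefined")
    f_norm = filtered.normalized
    r_norm = np.array(
        [reference.normalized_value(v) for v in filtered.order], dtype=float
    )
    return DisComparison(
        order=list(filtered.order),
        delta=f_norm - r_norm,
        filtered_normalized=f_norm.copy(),
        reference_normalized=r_norm,
    )


# ----------------------------------------------------------------------
# Bow-tie decomposition
# ----------------------------------------------------------------------

BOWTIE_LABELS = ("LSCC", "IN", "OUT", "OTHER")


@dataclass
class BowTie:
    """Bow-tie compartments of a directed network.

    LSCC is the largest strongly connected component (ties broken
    toward the one containing the lexicographically smallest vertex);
    IN reaches the LSCC, OUT is reached from it; vertices doing both
    without belonging to the LSCC, and everything else, are OTHER.
    ``degenerate`` flags networks whose largest SCC is a singleton.
    """

    labels: dict[str, str]
    lscc: set[str] = field(default_factory=set)
    degenerate: bool = False

    @property
    def sizes(self) -> dict[str, int]:
        out = {lab: 0 for lab in BOWTIE_LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def members(self, label: str) -> set[str]:
        return {v for v, lab in self.labels.items() if lab == label}

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("vertex\tcompartment\n")
            for v in sorted(self.labels):
                fh.write(f"{v}\t{self.labels[v]}\n")


def bowtie_decompose(net: DirectedNetwork) -> BowTie:
    """Partition the vertices into LSCC, IN, OUT and OTHER.

    If every strongly connected component is a singleton the result is
    flagged degenerate (all vertices OTHER) rather than silently
    picking an arbitrary one-vertex "core".
    """
    g = net.as_digraph()
    sccs = [set(c) for c in nx.strongly_connected_components(g)]
    if not sccs:
        return BowTie(labels={}, degenerate=True)
    max_size = max(len(c) for c in sccs)
    if max_size < 2:
        return BowTie(
            labels={v: "OTHER" for v in net.vertices}, degenerate=True
        )
    lscc = min(
        (c for c in sccs if len(c) == max_size), key=lambda c: min(c)
    )
    rep = next(iter(lscc))
    ancestors = nx.ancestors(g, rep)
    descendants = nx.descendants(g, rep)
    labels: dict[str, str] = {}
    for v in net.vertices:
        if v in lscc:
            labels[v] = "LSCC"
        elif v in ancestors and v in descendants:
            labels[v] = "OTHER"  # tube-like: both sides without membership
        elif v in ancestors:
            labels[v] = "IN"
        elif v in descendants:
            labels[v] = "OUT"
        else:
            labels[v] = "OTHER"
    return BowTie(labels=labels, lscc=set(lscc), degenerate=False)


# ----------------------------------------------------------------------
# Differential expression and variance homogeneity
# ----------------------------------------------------------------------


@dataclass
class DiffExpression:
    """Per-vertex log2 expression ratio between two conditions."""

    values: pd.Series  # index: vertex id
    numerator: str
    denominator: str
    pseudocount: float

    def to_tsv(self, path) -> None:
        out = self.values.sort_index()
        out.index.name = "vertex"
        out.rename("log2_fold_change").to_csv(
            path, sep="\t", float_format="%.10g"
        )


def log_fold_change(
    normal: ExpressionSet,
    disease: ExpressionSet,
    idmap: IdentifierMap,
    vertices: Optional[Iterable[str]] = None,
    c: float = 0.5,
    direction: str = "disease_vs_normal",
) -> DiffExpression:
    """Library-size-normalized log2 tag-count ratio per vertex.

    Counts are aggregated over all of a vertex' tags, converted to
    counts per million within each condition's library, and a
    pseudocount ``c`` (in CPM units) keeps the ratio finite when a
    vertex is absent from one condition.  The default sign is
    disease over normal; ``direction="normal_vs_disease"`` flips it.
    """
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    if direction not in ("disease_vs_normal", "normal_vs_disease"):
        raise ValueError(f"unknown direction {direction!r}")

    by_vertex: dict[str, list[str]] = {}
    for sid, vs in idmap.items():
        for v in vs:
            by_vertex.setdefault(v, []).append(sid)
    if vertices is None:
        vertices = by_vertex.keys()
    vertices = sorted(set(vertices))

    lib_n = max(normal.library_size, 1)
    lib_d = max(disease.library_size, 1)
    vals = {}
    for v in vertices:
        sids = by_vertex.get(v, [])
        cnt_n = sum(normal.counts.get(s, 0) for s in sids)
        cnt_d = sum(disease.counts.get(s, 0) for s in sids)
        cpm_n = cnt_n / lib_n * 1e6
        cpm_d = cnt_d / lib_d * 1e6
        lfc = math.log2((cpm_d + c) / (cpm_n + c))
        vals[v] = lfc if direction == "disease_vs_normal" else -lfc
    num, den = (
        (disease.condition, normal.condition)
        if direction == "disease_vs_normal"
        else (normal.condition, disease.condition)
    )
    return DiffExpression(
        values=pd.Series(vals, dtype=float),
        numerator=num,
        denominator=den,
        pseudocount=c,
    )


@dataclass
class LeveneResult:
    """Classical (mean-centered) Levene test for variance homogeneity."""

    W: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


def levene_test(groups: Sequence[Sequence[float]]) -> LeveneResult:
    """Mean-centered Levene test across two or more groups.

    Z_ij = |Y_ij - mean(Y_i)|; W is the one-way ANOVA F statistic of
    the Z values; p is the upper tail of F(g-1, N-g).  The classical
    mean-centered variant suits symmetric, moderate-tailed
    distributions such as log fold-changes.  When all absolute
    deviations are constant within groups the statistic is undefined
    and the result is flagged degenerate (except in the trivial case of
    identical spread, which gives W = 0, p = 1).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    g = len(gs)
    n_i = np.array([grp.size for grp in gs])
    N = int(n_i.sum())
    z = [np.abs(grp - grp.mean()) for grp in gs]
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = float(np.concatenate(z).mean())
    num = float((n_i * (zbar_i - zbar) ** 2).sum())
    den = float(sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbar_i)))
    df1, df2 = g - 1, N - g
    if num == 0.0:
        return LeveneResult(W=0.0, p=1.0, df_between=df1, df_within=df2)
    if den == 0.0:
        return LeveneResult(
            W=math.inf, p=0.0, df_between=df1, df_within=df2, degenerate=True
        )
    W = (df2 / df1) * num / den
    p = float(f_dist.sf(W, df1, df2))
    return LeveneResult(W=float(W), p=p, df_between=df1, df_within=df2)


def compartment_variance_report(
    bt: BowTie, de: DiffExpression, min_group_size: int = 2
) -> tuple[pd.DataFrame, LeveneResult]:
    """Differential-expression spread per bow-tie compartment.

    Groups the log fold-changes by compartment label, reports size,
    mean and variance per compartment with at least ``min_group_size``
    members, and tests the eligible compartments for equal variances
    with Levene's test.  Vertices without a compartment label are
    ignored.
    """
    by_label: dict[str, list[float]] = {}
    for v, val in de.values.items():
        lab = bt.labels.get(v)
        if lab is not None:
            by_label.setdefault(lab, []).append(float(val))
    eligible = {
        lab: vals
        for lab, vals in by_label.items()
        if len(vals) >= max(2, min_group_size)
    }
    if len(eligible) < 2:
        raise ValueError(
            f"need >=2 compartments with >={min_group_size} members, "
            f"got {len(eligible)}"
        )
    order = [lab for lab in BOWTIE_LABELS if lab in eligible]
    table = pd.DataFrame(
        {
            "compartment": order,
            "n": [len(eligible[lab]) for lab in order],
            "mean_lfc": [float(np.mean(eligible[lab])) for lab in order],
            "var_lfc": [float(np.var(eligible[lab], ddof=1)) for lab in order],
        }
    )
    lev = levene_test([eligible[lab] for lab in order])
    return table, lev
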