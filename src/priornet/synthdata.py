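"""Synthetic inputs with the statistical structure the pipeline assumes.

The real analysis runs on licensed or versioned resources (a curated
signaling reaction network, a metabolic reaction database, SAGE
tag-count libraries, a multi-tissue microarray intensity matrix).
This module generates stand-ins for all of them at the same scale and
with the features the downstream statistics rely on:

* a sparse directed reference network (~1800 vertices, ~3900 edges)
  with heavy-tailed out-degree and a planted strongly connected core,
  so bow-tie compartments are non-degenerate;
* ~137 pathways of mean size ~48, grown as topological balls so that
  pathway membership has the locality real pathways have;
* per-condition tag counts whose presence/absence pattern encodes a
  planted enriched pathway: enrichment lives in the *detection
  probability* (the pipeline is presence-based), not in fold-change;
* an 84-tissue intensity matrix providing the drawing weights;
* a reaction table with planted currency substrates for the metabolic
  construction.

Gene detection is modeled as a shared "expressed in this tissue" state
(probability chosen so the per-condition detection rate equals the
configured target) observed through a per-condition capture rate; the
two conditions therefore agree on most genes and their symmetric
difference stays small, as it does for two libraries from the same
tissue.  Tag counts are negative binomial (SAGE libraries are
over-dispersed).  Disease counts carry a per-vertex log2 fold-change
whose noise variance is inflated for vertices of the reference
network's bow-tie IN compartment, giving topology-correlated
differential-expression spread.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from priornet.netcore import DirectedNetwork, remove_orphans, write_network
from priornet.filtering import ExpressionSet, IdentifierMap
from priornet.metabolic import Reaction, ReactionTable
from priornet.enrichment import PathwayCollection, TissueExpressionMatrix
from priornet.topology import bowtie_decompose

import pandas as pd

__all__ = ["SimConfig", "SimData", "simulate_reference", "simulate_pathways",
           "simulate_expression", "simulate_reactions", "simulate_all"]

_CURRENCY_NAMES = ("ATP", "H2O", "NAD+", "ADP", "Pi", "CO2", "NADP+", "CoA")


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generator, with study-scale defaults."""

    seed: int = 0
    # reference network
    n_vertices: int = 1800
    n_edges: int = 3900
    core_size: int = 300
    in_size: int = 450
    out_size: int = 550
    # pathways
    n_pathways: int = 137
    mean_pathway_size: int = 48
    pathway_locality: float = 0.5
    planted_pathway_id: str = "PW_0001"
    # expression / detection
    n_tissues: int = 84
    detection_base_rate: float = 0.33
    capture_rate: float = 0.95
    enrichment_factor: float = 3.0
    library_size_normal: int = 50_000
    library_size_disease: int = 50_000
    nb_dispersion: float = 10.0
    abundance_mu_log: float = math.log(30.0)
    abundance_sigma_log: float = 0.8
    max_tags_per_vertex: int = 3
    max_spots_per_vertex: int = 2
    tissue_sigma_log: float = 1.0
    breast_tissue: str = "mammary_gland"
    breast_boost: float = 3.0
    breast_specific_fraction: float = 0.2
    lfc_sigma: float = 0.4
    variance_inflation: float = 4.0
    # reaction table
    n_enzymes: int = 120
    max_reactions_per_enzyme: int = 5
    n_substrates: int = 800
    max_substrate_use: int = 10
    n_currency: int = 5
    currency_reactions: int = 110

    def __post_init__(self) -> None:
        if not (0 <= self.pathway_locality <= 1):
            raise ValueError("pathway_locality must lie in [0, 1]")
        for name in ("detection_base_rate", "capture_rate",
                     "breast_specific_fraction"):
            val = getattr(self, name)
            if not (0 < val <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        for name in ("n_vertices", "n_edges", "core_size", "n_pathways",
                     "mean_pathway_size", "n_tissues", "n_enzymes",
                     "n_substrates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_edges > self.n_vertices * (self.n_vertices - 1):
            raise ValueError("n_edges exceeds the simple-digraph maximum")
        if self.core_size + self.in_size + self.out_size > self.n_vertices:
            raise ValueError("bow-tie compartment sizes exceed n_vertices")
        if self.n_edges < self.n_vertices:
            raise ValueError(
                "n_edges must at least cover the core cycle plus one "
                "anchoring edge per non-core vertex"
            )
        if self.n_currency > len(_CURRENCY_NAMES):
            raise ValueError(f"at most {len(_CURRENCY_NAMES)} currency substrates")

    def vertex_names(self) -> list[str]:
        return [f"v{i:04d}" for i in range(self.n_vertices)]


def _rng(cfg: SimConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


# ----------------------------------------------------------------------
# Reference network
# ----------------------------------------------------------------------


def simulate_reference(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> DirectedNetwork:
    """Sparse directed reference graph with a planted bow-tie skeleton.

    Vertex indices are partitioned into a strongly connected core
    (a random cycle, so the core is one SCC by construction), an IN
    pool whose members each carry an anchoring edge toward the core, an
    OUT pool anchored from the core, and a tendril remainder pointing
    into OUT.  Edges outside the core are kept acyclic (forward-ordered
    within each pool), so the largest SCC is exactly the planted core
    and the bow-tie compartments equal the pools.  The remaining edge
    budget attaches preferentially to high-out-degree sources (targets
    uniform within the compartment-respecting choices), yielding the
    heavy-tailed out-degree profile of curated signaling networks.
    """
    rng = _rng(cfg, rng)
    n, c = cfg.n_vertices, cfg.core_size
    in_end = c + cfg.in_size
    out_end = in_end + cfg.out_size
    names = cfg.vertex_names()
    edges: set[tuple[int, int]] = set()
    outdeg = np.zeros(n, dtype=float)

    def add(a: int, b: int) -> bool:
        if a != b and (a, b) not in edges:
            edges.add((a, b))
            outdeg[a] += 1
            return True
        return False

    perm = rng.permutation(c)
    for a, b in zip(perm, np.roll(perm, -1)):
        add(int(a), int(b))

    def pick_from(ranges: list[tuple[int, int]]) -> int:
        sizes = [hi - lo for lo, hi in ranges if hi > lo]
        ranges = [(lo, hi) for lo, hi in ranges if hi > lo]
        u = int(rng.integers(sum(sizes)))
        for (lo, hi), s in zip(ranges, sizes):
            if u < s:
                return lo + u
            u -= s
        raise AssertionError("unreachable")

    # anchoring edges: guarantee each pool vertex its compartment role
    for v in range(c, in_end):  # IN reaches the core
        add(v, pick_from([(0, c), (v + 1, in_end)]))
    for v in range(in_end, out_end):  # OUT is reached from the core
        add(pick_from([(0, c), (in_end, v)]), v)
    for v in range(out_end, n):  # tendrils point into OUT
        add(v, pick_from([(in_end, out_end), (v + 1, n)]))

    def allowed(v: int) -> list[tuple[int, int]]:
        if v < c:  # core -> core or OUT
            return [(0, v), (v + 1, c), (in_end, out_end)]
        if v < in_end:  # IN -> core or forward-IN
            return [(0, c), (v + 1, in_end)]
        if v < out_end:  # OUT -> forward-OUT
            return [(v + 1, out_end)]
        return [(in_end, out_end), (v + 1, n)]  # tendril -> OUT or forward

    capacity = np.array(
        [sum(hi - lo for lo, hi in allowed(v)) for v in range(n)], dtype=float
    )
    attempts = 0
    while len(edges) < cfg.n_edges:
        attempts += 1
        if attempts > 200 * cfg.n_edges:
            raise RuntimeError("edge budget infeasible for the planted layout")
        w = np.where(capacity > 0, outdeg + 1.0, 0.0)
        src = int(rng.choice(n, p=w / w.sum()))
        add(src, pick_from(allowed(src)))

    net = DirectedNetwork(name="synthetic_reference")
    for v in names:
        net.add_vertex(v)
    for a, b in sorted(edges):
        net.add_edge(names[a], names[b])
    return net


# ----------------------------------------------------------------------
# Pathways
# ----------------------------------------------------------------------


def simulate_pathways(
    net: DirectedNetwork, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> PathwayCollection:
    """Vertex sets with shifted-Poisson sizes and mild topological locality.

    Each pathway grows around a seed vertex: every new member is drawn
    from the current ball's undirected frontier with probability
    ``pathway_locality`` (else uniformly from the whole network), so
    membership is topologically clustered without collapsing into a
    pure graph ball.  When the frontier is exhausted the remainder is
    filled uniformly, so the configured size is always reached.
    """
    rng = _rng(cfg, rng)
    order = sorted(net.vertices)
    n = len(order)
    nbrs = {
        v: sorted(net.in_neighbors(v) | net.out_neighbors(v)) for v in order
    }
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for idx in range(cfg.n_pathways):
        size = 1 + int(rng.poisson(cfg.mean_pathway_size - 1))
        size = min(max(size, 1), n)
        seed_v = order[int(rng.integers(n))]
        members = {seed_v}
        frontier = [u for u in nbrs[seed_v] if u not in members]
        while len(members) < size:
            pick = None
            if frontier and rng.random() < cfg.pathway_locality:
                pick = frontier.pop(int(rng.integers(len(frontier))))
                if pick in members:
                    continue
            else:
                cand = order[int(rng.integers(n))]
                if cand in members:
                    continue
                pick = cand
            members.add(pick)
            frontier.extend(u for u in nbrs[pick] if u not in members)
        name = f"PW_{idx + 1:04d}"
        sets[name] = members
        desc[name] = "synthetic ball-grown pathway"
    return PathwayCollection(sets, desc)


# ----------------------------------------------------------------------
# Expression data
# ----------------------------------------------------------------------


def simulate_expression(
    net: DirectedNetwork,
    pathways: PathwayCollection,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionSet, ExpressionSet, IdentifierMap, TissueExpressionMatrix]:
    """Tag counts for two conditions, an id map and a tissue matrix.

    Detection: each vertex has a per-condition target detection
    probability (base rate, multiplied by the enrichment factor and
    capped at 1 for planted-pathway members); a shared expression state
    observed through the capture rate realizes it, correlating the two
    conditions.  Counts: negative binomial around a library-scaled
    log-normal abundance; the disease condition multiplies the
    abundance by 2**delta with delta drawn per vertex, its variance
    inflated for IN-compartment vertices of the reference bow-tie.
    """
    rng = _rng(cfg, rng)
    if cfg.planted_pathway_id not in pathways:
        raise KeyError(f"planted pathway {cfg.planted_pathway_id!r} not found")
    planted = pathways[cfg.planted_pathway_id]
    order = sorted(net.vertices)
    n = len(order)
    pos = {v: i for i, v in enumerate(order)}

    pruned = remove_orphans(net)
    bt = (
        bowtie_decompose(pruned)
        if pruned.n_vertices >= 2
        else None
    )
    in_compartment = np.zeros(n, dtype=bool)
    if bt is not None and not bt.degenerate:
        for v in bt.members("IN"):
            in_compartment[pos[v]] = True

    # detection probabilities
    target = np.full(n, cfg.detection_base_rate)
    planted_mask = np.zeros(n, dtype=bool)
    for v in planted:
        planted_mask[pos[v]] = True
    target[planted_mask] = min(
        cfg.detection_base_rate * cfg.enrichment_factor, 1.0
    )
    p_expressed = np.minimum(target / cfg.capture_rate, 1.0)
    expressed = rng.random(n) < p_expressed
    det_normal = expressed & (rng.random(n) < cfg.capture_rate)
    det_disease = expressed & (rng.random(n) < cfg.capture_rate)

    # abundances and differential expression
    abundance = rng.lognormal(cfg.abundance_mu_log, cfg.abundance_sigma_log, n)
    sigma = np.where(
        in_compartment,
        cfg.lfc_sigma * math.sqrt(cfg.variance_inflation),
        cfg.lfc_sigma,
    )
    delta = rng.normal(0.0, sigma)
    mean_normal = abundance
    mean_disease = abundance * np.power(2.0, delta)

    # tags and id map
    n_tags = rng.integers(1, cfg.max_tags_per_vertex + 1, size=n)
    idmap_pairs = []
    tag_names: list[list[str]] = []
    for i, v in enumerate(order):
        tags = [f"tag_{v}_{t}" for t in range(n_tags[i])]
        tag_names.append(tags)
        idmap_pairs.extend((t, v) for t in tags)
    idmap = IdentifierMap(idmap_pairs)

    def _counts(mean_vec, detected, library_size):
        scale = library_size / max(float(mean_vec[detected].sum()), 1.0)
        counts: dict[str, int] = {}
        r = cfg.nb_dispersion
        for i in np.flatnonzero(detected):
            mu = mean_vec[i] * scale / n_tags[i]
            p_nb = r / (r + mu)
            draws = rng.negative_binomial(r, p_nb, size=n_tags[i])
            draws[0] = max(draws[0], 1)  # detected => at least one tag
            for tag, cnt in zip(tag_names[i], draws):
                if cnt > 0:
                    counts[tag] = int(cnt)
        return counts

    normal = ExpressionSet(
        condition="normal",
        counts=_counts(mean_normal, det_normal, cfg.library_size_normal),
    )
    disease = ExpressionSet(
        condition="disease",
        counts=_counts(mean_disease, det_disease, cfg.library_size_disease),
    )

    # tissue matrix
    tissues = [cfg.breast_tissue] + [
        f"tissue_{j:02d}" for j in range(1, cfg.n_tissues)
    ]
    breast_specific = rng.random(n) < cfg.breast_specific_fraction
    spot_rows = {}
    spot_map: dict[str, set[str]] = {}
    n_spots = rng.integers(1, cfg.max_spots_per_vertex + 1, size=n)
    for i, v in enumerate(order):
        for s in range(n_spots[i]):
            spot = f"spot_{v}_{s}"
            row = rng.lognormal(0.0, cfg.tissue_sigma_log, cfg.n_tissues)
            if breast_specific[i]:
                row[0] *= cfg.breast_boost
            spot_rows[spot] = row
            spot_map[spot] = {v}
    values = pd.DataFrame.from_dict(
        spot_rows, orient="index", columns=tissues
    ).sort_index()
    tm = TissueExpressionMatrix(values, spot_map)
    return normal, disease, idmap, tm


# ----------------------------------------------------------------------
# Reaction table
# ----------------------------------------------------------------------


def simulate_reactions(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> ReactionTable:
    """Reaction records with planted currency substrates.

    Each enzyme catalyzes 1-5 reactions over a substrate pool in which
    ordinary substrates are capped at ``max_substrate_use`` reactions,
    while each designated currency substrate is spliced into more than
    100 reactions; reversibility is a fair coin.
    """
    rng = _rng(cfg, rng)
    enzymes = [
        f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 10))}."
        f"{int(rng.integers(1, 10))}.{i + 1}"
        for i in range(cfg.n_enzymes)
    ]
    pool = [f"S{i:04d}" for i in range(cfg.n_substrates)]
    usage = np.zeros(cfg.n_substrates, dtype=int)

    def draw_substrates(k: int, exclude: set[int]) -> list[int]:
        avail = np.flatnonzero(usage < cfg.max_substrate_use)
        avail = np.array([a for a in avail if a not in exclude])
        if avail.size < k:
            raise RuntimeError("substrate pool exhausted; enlarge n_substrates")
        picked = rng.choice(avail, size=k, replace=False)
        usage[picked] += 1
        return [int(x) for x in picked]

    records: list[dict] = []
    rid = 0
    for enzyme in enzymes:
        for _ in range(int(rng.integers(1, cfg.max_reactions_per_enzyme + 1))):
            rid += 1
            educts = draw_substrates(int(rng.integers(1, 4)), set())
            products = draw_substrates(int(rng.integers(1, 4)), set(educts))
            records.append(
                {
                    "reaction_id": f"R{rid:04d}",
                    "enzyme_id": enzyme,
                    "educts": {pool[i] for i in educts},
                    "products": {pool[i] for i in products},
                    "reversible": bool(rng.random() < 0.5),
                }
            )

    if len(records) < cfg.currency_reactions:
        raise RuntimeError(
            f"only {len(records)} reactions generated; cannot plant currency "
            f"substrates into {cfg.currency_reactions}"
        )
    for name in _CURRENCY_NAMES[: cfg.n_currency]:
        chosen = rng.choice(len(records), size=cfg.currency_reactions, replace=False)
        for j in chosen:
            side = "educts" if rng.random() < 0.5 else "products"
            records[j][side] = set(records[j][side]) | {name}

    return ReactionTable(
        Reaction(
            reaction_id=r["reaction_id"],
            enzyme_id=r["enzyme_id"],
            educts=frozenset(r["educts"]),
            products=frozenset(r["products"]),
            reversible=r["reversible"],
        )
        for r in records
    )


# ----------------------------------------------------------------------
# One-call generation and serialization
# ----------------------------------------------------------------------


@dataclass
class SimData:
    """All generated inputs of one simulation run."""

    config: SimConfig
    reference: DirectedNetwork
    pathways: PathwayCollection
    normal: ExpressionSet
    disease: ExpressionSet
    idmap: IdentifierMap
    tissue: TissueExpressionMatrix
    reactions: ReactionTable

    def write(self, outdir) -> None:
        """Emit every input in the format the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_network(self.reference, outdir / "reference.sif", "sif")
        self.pathways.to_gmt(outdir / "pathways.gmt")
        self.normal.to_tsv(outdir / "expression_normal.tsv")
        self.disease.to_tsv(outdir / "expression_disease.tsv")
        self.idmap.to_tsv(outdir / "idmap.tsv")
        self.tissue.to_tsv(outdir / "tissue_matrix.tsv", outdir / "spot_map.tsv")
        self.reactions.to_tsv(outdir / "reactions.tsv")
        manifest = {
            "generator": "priornet.synthdata",
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_all(cfg: SimConfig) -> SimData:
    """Generate every pipeline input from one seed, in a fixed order."""
    rng = np.random.default_rng(cfg.seed)
    reference = simulate_reference(cfg, rng)
    pathways = simulate_pathways(reference, cfg, rng)
    normal, disease, idmap, tissue = simulate_expression(
        reference, pathways, cfg, rng
    )
    reactions = simulate_reactions(cfg, rng)
    return SimData(
        config=cfg,
        reference=reference,
        pathways=pathways,
        normal=normal,
        disease=disease,
        idmap=idmap,
        tissue=tissue,
        reactions=reactions,
    )
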