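"""Expression-to-network mapping, strict and k-extended filtering.

Detection is presence-based: a gene counts as detected when at least
one of its expression-platform identifiers (e.g. SAGE tags) reaches
the tag-count threshold (default: one tag).  Detected identifiers are
mapped onto reference-network vertices through a many-to-many
identifier map, and the reference network is restricted to the induced
subgraph on the detected vertices (strict filtering) or on their
k-step in/out neighborhood (k-extended filtering).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from priornet.netcore import DirectedNetwork


@dataclass
class ExpressionSet:
    """Per-identifier tag counts for one condition (e.g. one SAGE pool)."""

    condition: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, path, condition: str | None = None) -> "ExpressionSet":
        """Read a 2-column TSV ``source_id<TAB>count`` (header optional)."""
        path = Path(path)
        counts: dict[str, int] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                if lineno == 1 and parts[0] == "source_id":
                    continue
                counts[parts[0]] = counts.get(parts[0], 0) + int(parts[1])
        return cls(condition=condition or path.stem, counts=counts)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_id\tcount\n")
            for sid in sorted(self.counts):
                fh.write(f"{sid}\t{self.counts[sid]}\n")


class IdentifierMap:
    """Many-to-many map from expression-platform ids to network vertex ids.

    Lookup of an unmapped source id returns the empty set, never an
    error.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._fwd: dict[str, set[str]] = {}
        for src, vid in pairs:
            self._fwd.setdefault(src, set()).add(vid)

    def __getitem__(self, source_id: str) -> set[str]:
        return set(self._fwd.get(source_id, set()))

    def __contains__(self, source_id: str) -> bool:
        return source_id in self._fwd

    def __len__(self) -> int:
        return len(self._fwd)

    def source_ids(self) -> set[str]:
        return set(self._fwd)

    def items(self):
        return ((s, set(vs)) for s, vs in self._fwd.items())

    def vertices_for(self, source_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for sid in source_ids:
            out |= self._fwd.get(sid, set())
        return out

    @classmethod
    def from_tsv(cls, path) -> "IdentifierMap":
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "source_id":
                    continue
                pairs.append((row[0], row[1]))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_id\tvertex_id\n")
            for src in sorted(self._fwd):
                for vid in sorted(self._fwd[src]):
                    fh.write(f"{src}\t{vid}\n")


@dataclass
class DetectionSet:
    """Vertices of the reference network detected under one condition.

    ``n_unmapped`` counts source ids with no map entry;
    ``n_out_of_reference`` counts source ids all of whose mapped vertex
    ids are absent from the reference network.
    """

    condition: str
    detected: set[str] = field(default_factory=set)
    n_unmapped: int = 0
    n_out_of_reference: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    def report_tsv(self, path) -> None:
        """Per-source-id provenance: detected / unmapped / out-of-reference."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_id\tstatus\n")
            for sid in sorted(self.provenance):
                fh.write(f"{sid}\t{self.provenance[sid]}\n")


def map_detection(
    expr: ExpressionSet,
    idmap: IdentifierMap,
    ref: DirectedNetwork,
    threshold: int = 1,
) -> DetectionSet:
    """Map detected expression identifiers onto reference vertices.

    A vertex is detected iff at least one of its source ids has a count
    of at least ``threshold`` tags.  Source ids below the threshold are
    ignored entirely (they appear in the provenance as ``below_threshold``
    but are not tallied as unmapped).
    """
    det = DetectionSet(condition=expr.condition)
    ref_vertices = ref.vertices
    for sid in sorted(expr.counts):
        if expr.counts[sid] < threshold:
            det.provenance[sid] = "below_threshold"
            continue
        mapped = idmap[sid]
        if not mapped:
            det.n_unmapped += 1
            det.provenance[sid] = "unmapped"
            continue
        in_ref = mapped & ref_vertices
        if not in_ref:
            det.n_out_of_reference += 1
            det.provenance[sid] = "out_of_reference"
            continue
        det.detected |= in_ref
        det.provenance[sid] = "detected"
    return det


def combine_conditions(
    normal: DetectionSet, disease: DetectionSet
) -> dict[str, DetectionSet]:
    """Set algebra on two conditions' detected vertex sets.

    Returns a dict with keys ``union``, ``intersection`` and
    ``symmetric_difference``.  The union is the default analysis set:
    it minimizes fragmentation and maximizes vertex count, retaining
    silenced as well as induced genes.
    """
    ops = {
        "union": normal.detected | disease.detected,
        "intersection": normal.detected & disease.detected,
        "symmetric_difference": normal.detected ^ disease.detected,
    }
    out = {}
    for name, vs in ops.items():
        out[name] = DetectionSet(
            condition=f"{name}({normal.condition},{disease.condition})",
            detected=set(vs),
        )
    return out


def strict_filter(ref: DirectedNetwork, det: DetectionSet | set) -> DirectedNetwork:
    """Induced subgraph of the reference on the detected vertex set."""
    detected = det.detected if isinstance(det, DetectionSet) else set(det)
    extra = detected - ref.vertices
    if extra:
        raise KeyError(f"detected vertices not in reference: {sorted(extra)[:5]}")
    name = det.condition if isinstance(det, DetectionSet) else "strict"
    return ref.induced_subgraph(detected, name=f"strict[{name}]")


def extend(ref: DirectedNetwork, seed: Iterable[str], k: int = 1) -> set[str]:
    """k-step extension of a vertex set within the reference network.

    One step adds all in- and out-neighbors of the current set; ``k=0``
    returns the seed unchanged.  The induced subgraph on the result is
    the k-extended network (the 2-neighborhood is literally
    ``extend(extend(S))``).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    current = set(seed)
    for v in current:
        if not ref.has_vertex(v):
            raise KeyError(f"seed vertex not in reference network: {v!r}")
    g = ref.as_digraph()
    for _ in range(k):
        nxt = set(current)
        for v in current:
            nxt.update(g.predecessors(v))
            nxt.update(g.successors(v))
        if nxt == current:
            break
        current = nxt
    return current


def extended_network(
    ref: DirectedNetwork, det: DetectionSet | set, k: int = 1
) -> DirectedNetwork:
    """Convenience: induced subgraph on the k-extended detected set."""
    detected = det.detected if isinstance(det, DetectionSet) else set(det)
    vs = extend(ref, detected, k)
    name = det.condition if isinstance(det, DetectionSet) else "set"
    return ref.induced_subgraph(vs, name=f"{k}-extended[{name}]")
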