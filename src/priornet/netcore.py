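"""Directed-network data model, file I/O and basic connectivity utilities.

The :class:`DirectedNetwork` is a thin, deterministic wrapper around a
:class:`networkx.DiGraph`.  Edges carry an optional semantic label
(e.g. ``activation`` / ``inhibition``) as metadata; all topological
computations in this package are label-blind, and parallel edges that
differ only in their label count as a single edge topologically.
Self-loops are not permitted: the pair-connectivity semantics used
downstream (ordered pairs of *distinct* vertices) make them inert, so
they are dropped at ingestion with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

FORMATS = ("sif", "edgelist")


class NetworkParseError(ValueError):
    """Raised for a malformed line in a network file; names the line number."""


class DirectedNetwork:
    """A directed graph with string vertex identifiers and labeled edges.

    Parameters
    ----------
    name:
        Free-text name carried along for reporting; ignored by equality.
    """

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_vertex(self, v: str) -> None:
        self._g.add_node(v)

    def add_edge(self, u: str, v: str, label: Optional[str] = None) -> None:
        """Add the directed edge ``u -> v``.

        A repeated (u, v, label) triple is a no-op; a different label on
        an existing (u, v) pair is stored alongside the first one but
        the pair still counts once topologically.
        """
        if u == v:
            raise ValueError(f"self-loop not permitted: {u!r}")
        if self._g.has_edge(u, v):
            self._g.edges[u, v]["labels"].add(label)
        else:
            self._g.add_edge(u, v, labels={label})

    # -- basic queries -------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Label-blind edge count (ordered vertex pairs)."""
        return self._g.number_of_edges()

    def has_vertex(self, v: str) -> bool:
        return self._g.has_node(v)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def edge_labels(self, u: str, v: str) -> set[Optional[str]]:
        return set(self._g.edges[u, v]["labels"])

    def edges(self) -> Iterator[tuple[str, str]]:
        """Iterate over the label-blind edge pairs."""
        return iter(self._g.edges())

    def edge_records(self) -> list[tuple[str, Optional[str], str]]:
        """All (source, label, target) triples in lexicographic order."""
        recs = []
        for u, v, data in self._g.edges(data=True):
            for lab in data["labels"]:
                recs.append((u, lab, v))
        return sorted(recs, key=lambda r: (r[0], r[2], r[1] or ""))

    def in_neighbors(self, v: str) -> set[str]:
        return set(self._g.predecessors(v))

    def out_neighbors(self, v: str) -> set[str]:
        return set(self._g.successors(v))

    def degree(self, v: str) -> int:
        return self._g.in_degree(v) + self._g.out_degree(v)

    # -- derived networks ----------------------------------------------

    def induced_subgraph(self, vs: Iterable[str], name: str = "") -> "DirectedNetwork":
        vs = set(vs)
        missing = vs - self.vertices
        if missing:
            raise KeyError(f"vertices not in network: {sorted(missing)[:5]}")
        sub = DirectedNetwork(name=name or self.name)
        for v in vs:
            sub.add_vertex(v)
        for u, v, data in self._g.edges(data=True):
            if u in vs and v in vs:
                for lab in data["labels"]:
                    sub.add_edge(u, v, lab)
        return sub

    def copy(self) -> "DirectedNetwork":
        return self.induced_subgraph(self.vertices, name=self.name)

    def as_digraph(self) -> nx.DiGraph:
        """The underlying label-blind :class:`networkx.DiGraph` (shared)."""
        return self._g

    # -- dunder --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return (
            self.vertices == other.vertices
            and self.edge_records() == other.edge_records()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DirectedNetwork(name={self.name!r}, "
            f"n_vertices={self.n_vertices}, n_edges={self.n_edges})"
        )

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, Optional[str]]],
        vertices: Iterable[str] = (),
        name: str = "",
    ) -> "DirectedNetwork":
        """Build a network from edge tuples ``(u, v)`` or ``(u, v, label)``."""
        net = cls(name=name)
        for v in vertices:
            net.add_vertex(v)
        for e in edges:
            if len(e) == 2:
                u, v = e
                lab = None
            else:
                u, v, lab = e
            net.add_edge(u, v, lab)
        return net


@dataclass
class ComponentPartition:
    """Weakly connected components of a directed network.

    Components are numbered deterministically: by decreasing size, ties
    by the lexicographically smallest member.
    """

    component_of: dict[str, int]
    sizes: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    def members(self, cid: int) -> set[str]:
        return {v for v, c in self.component_of.items() if c == cid}


# ----------------------------------------------------------------------
# File I/O
#
# SIF: 3 columns (source, interaction label, target); a line with a
# single field declares a lone vertex (standard SIF convention), which
# is what makes the round trip exact for networks with orphans.  The
# label "-" is reserved for "no label".  Edge list: 2 columns, or a
# single field for a lone vertex.  '#' starts a comment line.
# ----------------------------------------------------------------------

_NO_LABEL = "-"


def _parse_lines(path: Path, fmt: str):
    n_loops = 0
    net = DirectedNetwork(name=Path(path).stem)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                net.add_vertex(fields[0])
                continue
            if fmt == "sif":
                if len(fields) < 3:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: SIF needs 1 or >=3 fields, "
                        f"got {len(fields)}"
                    )
                src, lab = fields[0], fields[1]
                label = None if lab == _NO_LABEL else lab
                targets = fields[2:]
            else:
                src, label = fields[0], None
                targets = [fields[1]]
            net.add_vertex(src)
            for tgt in targets:
                net.add_vertex(tgt)
                if src == tgt:
                    n_loops += 1
                    continue
                net.add_edge(src, tgt, label)
    if n_loops:
        logger.info("%s: dropped %d self-loop line(s)", path, n_loops)
    return net


def read_network(path, format: str = "sif") -> DirectedNetwork:
    """Read a directed network from a SIF or 2-column edge-list file.

    Duplicate lines collapse to one edge; self-loop lines are dropped
    (with a logged count) while the vertex is retained as an orphan.
    An empty file yields an empty network.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    return _parse_lines(path, format)


def write_network(net: DirectedNetwork, path, format: str = "sif") -> None:
    """Write ``net`` so that :func:`read_network` reproduces it exactly.

    Lines are emitted in lexicographic order, so output is
    bit-reproducible.  Lone vertices are written as single-field lines.
    Writing a labeled network as ``edgelist`` discards the labels.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    covered: set[str] = set()
    lines: list[str] = []
    if format == "sif":
        for u, lab, v in net.edge_records():
            lines.append(f"{u}\t{lab if lab is not None else _NO_LABEL}\t{v}")
            covered.update((u, v))
    else:
        for u, v in sorted(net.edges()):
            lines.append(f"{u}\t{v}")
            covered.update((u, v))
    for v in sorted(net.vertices - covered):
        lines.append(v)
    lines.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


# ----------------------------------------------------------------------
# Connectivity utilities
# ----------------------------------------------------------------------


def weak_components(net: DirectedNetwork) -> ComponentPartition:
    """Partition the vertex set into weakly connected components."""
    comps = [set(c) for c in nx.weakly_connected_components(net.as_digraph())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    component_of = {}
    for cid, comp in enumerate(comps):
        for v in comp:
            component_of[v] = cid
    return ComponentPartition(component_of=component_of, sizes=[len(c) for c in comps])


def remove_orphans(net: DirectedNetwork) -> DirectedNetwork:
    """Drop vertices with no incident edges.

    Removing an orphan changes no connectivity, so topological scorings
    (pairwise disconnectivity, bow-tie) operate on the pruned network;
    enrichment universes keep the orphans.
    """
    keep = {v for v in net.vertices if net.degree(v) > 0}
    return net.induced_subgraph(keep, name=net.name)
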