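"""Enzyme-centered metabolic network construction from a reaction table.

Vertices are enzyme activities (EC-number-like identifiers); a directed
edge E1 -> E2 records a shared substrate that is a product of a
reaction catalyzed by E1 and an educt of a reaction catalyzed by E2.
Ubiquitous "currency" substrates (ATP, water, ...) taking part in more
than a threshold number of reactions are excluded from edge
construction, since they would connect nearly everything with
everything.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from priornet.netcore import DirectedNetwork


@dataclass(frozen=True)
class Reaction:
    """One reaction record: enzyme, educts, products, reversibility."""

    reaction_id: str
    enzyme_id: str
    educts: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.enzyme_id:
            raise ValueError(f"{self.reaction_id}: reaction needs an enzyme")
        if not self.educts or not self.products:
            raise ValueError(
                f"{self.reaction_id}: reaction needs >=1 educt and >=1 product"
            )


class ReactionTable:
    """A list of :class:`Reaction` records with TSV I/O.

    TSV columns: reaction_id, enzyme_id, educts (semicolon-joined),
    products (semicolon-joined), reversible (0/1).
    """

    def __init__(self, reactions: Iterable[Reaction] = ()) -> None:
        self.reactions: list[Reaction] = list(reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    @property
    def enzymes(self) -> set[str]:
        return {r.enzyme_id for r in self.reactions}

    @classmethod
    def from_tsv(cls, path) -> "ReactionTable":
        path = Path(path)
        reactions = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "reaction_id":
                    continue
                if len(parts) < 5:
                    raise ValueError(f"{path}: line {lineno}: expected 5 columns")
                reactions.append(
                    Reaction(
                        reaction_id=parts[0],
                        enzyme_id=parts[1],
                        educts=frozenset(parts[2].split(";")),
                        products=frozenset(parts[3].split(";")),
                        reversible=bool(int(parts[4])),
                    )
                )
        return cls(reactions)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("reaction_id\tenzyme_id\teducts\tproducts\treversible\n")
            for r in sorted(self.reactions, key=lambda r: r.reaction_id):
                fh.write(
                    f"{r.reaction_id}\t{r.enzyme_id}\t"
                    f"{';'.join(sorted(r.educts))}\t"
                    f"{';'.join(sorted(r.products))}\t"
                    f"{int(r.reversible)}\n"
                )


def substrate_reaction_counts(rt: ReactionTable) -> dict[str, int]:
    """Number of distinct reaction records each substrate participates in.

    A substrate appearing as both educt and product of the same
    reaction counts once for that reaction.  Counts are taken on the
    raw records, before any currency filtering and before expanding
    reversible reactions.
    """
    counter: Counter[str] = Counter()
    for r in rt:
        for s in r.educts | r.products:
            counter[s] += 1
    return dict(counter)


def build_enzyme_network(
    rt: ReactionTable, currency_threshold: int = 100
) -> DirectedNetwork:
    """Build the enzyme adjacency network from a reaction table.

    A directed edge E1 -> E2 exists iff some non-currency substrate s
    is a product of a reaction of E1 and an educt of a reaction of E2.
    Substrates taking part in more than ``currency_threshold`` reactions
    are discarded from edge construction (their enzymes stay as
    vertices).  Reversible reactions contribute both orientations of
    their educt/product sets.  Self-loops (E1 == E2) are excluded.
    """
    if currency_threshold < 1:
        raise ValueError("currency_threshold must be >= 1")
    counts = substrate_reaction_counts(rt)
    currency = {s for s, c in counts.items() if c > currency_threshold}

    producers: dict[str, set[str]] = {}  # substrate -> enzymes producing it
    consumers: dict[str, set[str]] = {}  # substrate -> enzymes consuming it
    net = DirectedNetwork(name="enzyme_network")
    for r in rt:
        net.add_vertex(r.enzyme_id)
        orientations = [(r.educts, r.products)]
        if r.reversible:
            orientations.append((r.products, r.educts))
        for educts, products in orientations:
            for s in products - currency:
                producers.setdefault(s, set()).add(r.enzyme_id)
            for s in educts - currency:
                consumers.setdefault(s, set()).add(r.enzyme_id)

    for s, prods in producers.items():
        cons = consumers.get(s)
        if not cons:
            continue
        for e1 in prods:
            for e2 in cons:
                if e1 != e2 and not net.has_edge(e1, e2):
                    net.add_edge(e1, e2, label=None)
    return net
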