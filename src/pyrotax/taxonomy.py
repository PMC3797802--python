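"""Ranked bacterial taxonomy shared by the simulator and all three assigners.

The tree is fixed-depth: domain > phylum > class > order > family > genus.
Genus nodes may carry a *candidate* flag for provisionally named taxa
(e.g. 'Accumulibacter') that formal taxonomies do not recognise; such genera
are reachable only through best-hit assignment, never through the naive-Bayes
or lowest-common-ancestor routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")
RANK_INDEX = {r: i for i, r in enumerate(RANKS)}
_GG_PREFIX = ("k", "p", "c", "o", "f", "g")

#: A lineage is a tuple of names, root-first, one per rank, possibly truncated.
Lineage = tuple[str, ...]


@dataclass
class TaxonNode:
    id: int
    name: str
    rank: str
    parent: Optional[int]
    candidate: bool = False


class TaxonomyError(ValueError):
    pass


class TaxonomyTree:
    """Container for ranked taxon nodes with lineage lookups.

    Invariants (checked by :meth:`validate`): exactly one root at rank domain,
    every genus has one ancestor per rank, and names are unique within a rank.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {n.id: n for n in nodes}
        self._children: dict[Optional[int], list[int]] = {}
        for n in self.nodes.values():
            self._children.setdefault(n.parent, []).append(n.id)
        self._by_rank_name: dict[tuple[str, str], TaxonNode] = {}
        for n in self.nodes.values():
            key = (n.rank, n.name)
            if key in self._by_rank_name:
                raise TaxonomyError(f"duplicate name {n.name!r} at rank {n.rank}")
            self._by_rank_name[key] = n
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_lineages(cls, lineages: Iterable[Sequence[str]],
                      candidates: Iterable[str] = ()) -> "TaxonomyTree":
        """Build a tree from full 6-rank lineages (e.g. parsed Greengenes rows)."""
        cand = set(candidates)
        nodes: dict[Lineage, TaxonNode] = {}
        next_id = 0
        for lin in lineages:
            lin = tuple(lin)
            if len(lin) != len(RANKS):
                raise TaxonomyError(f"lineage {lin} does not span all ranks")
            for depth in range(1, len(lin) + 1):
                prefix = lin[:depth]
                if prefix in nodes:
                    continue
                parent = nodes[prefix[:-1]].id if depth > 1 else None
                nodes[prefix] = TaxonNode(
                    id=next_id, name=lin[depth - 1], rank=RANKS[depth - 1],
                    parent=parent, candidate=(depth == 6 and lin[-1] in cand))
                next_id += 1
        return cls(nodes.values())

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].rank != "domain":
            raise TaxonomyError("tree must have exactly one domain-rank root")
        for n in self.nodes.values():
            if n.rank not in RANK_INDEX:
                raise TaxonomyError(f"unknown rank {n.rank!r}")
            if n.parent is not None:
                parent = self.nodes.get(n.parent)
                if parent is None:
                    raise TaxonomyError(f"dangling parent for node {n.id}")
                if RANK_INDEX[parent.rank] != RANK_INDEX[n.rank] - 1:
                    raise TaxonomyError(
                        f"node {n.name} at {n.rank} under {parent.rank} parent")
            if n.candidate and n.rank != "genus":
                raise TaxonomyError("candidate flag is restricted to genus nodes")

    # -- queries ------------------------------------------------------------

    @property
    def root(self) -> TaxonNode:
        return next(n for n in self.nodes.values() if n.parent is None)

    def children(self, node_id: Optional[int]) -> list[TaxonNode]:
        return [self.nodes[i] for i in self._children.get(node_id, [])]

    def genera(self, include_candidates: bool = True) -> list[TaxonNode]:
        out = [n for n in self.nodes.values() if n.rank == "genus"]
        if not include_candidates:
            out = [n for n in out if not n.candidate]
        return sorted(out, key=lambda n: n.name)

    def find(self, rank: str, name: str) -> Optional[TaxonNode]:
        return self._by_rank_name.get((rank, name))

    def lineage_of(self, node: TaxonNode) -> Lineage:
        """Root-first name path for a node."""
        path = []
        cur: Optional[TaxonNode] = node
        while cur is not None:
            path.append(cur.name)
            cur = self.nodes[cur.parent] if cur.parent is not None else None
        return tuple(reversed(path))

    def genus_lineage(self, genus_name: str) -> Lineage:
        node = self.find("genus", genus_name)
        if node is None:
            raise TaxonomyError(f"genus {genus_name!r} not in taxonomy")
        return self.lineage_of(node)

    def is_candidate(self, genus_name: str) -> bool:
        node = self.find("genus", genus_name)
        return bool(node and node.candidate)


def lowest_common_ancestor(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest shared rank-path prefix of the given lineages."""
    if not lineages:
        return ()
    common = list(lineages[0])
    for lin in lineages[1:]:
        depth = 0
        for a, b in zip(common, lin):
            if a != b:
                break
            depth += 1
        common = common[:depth]
    return tuple(common)


def format_greengenes(lineage: Lineage) -> str:
    """Serialize a lineage as ``k__X;p__X;...;g__X`` (empty fields for truncation)."""
    fields = []
    for i, prefix in enumerate(_GG_PREFIX):
        name = lineage[i] if i < len(lineage) else ""
        fields.append(f"{prefix}__{name}")
    return ";".join(fields)


def parse_greengenes(text: str) -> Lineage:
    """Parse ``k__X;p__X;...`` into a (possibly truncated) lineage tuple."""
    names = []
    for i, fieldstr in enumerate(text.strip().split(";")):
        fieldstr = fieldstr.strip()
        expected = _GG_PREFIX[i] + "__"
        if not fieldstr.startswith(expected):
            raise TaxonomyError(f"malformed lineage field {fieldstr!r}")
        name = fieldstr[len(expected):]
        if not name:
            break
        names.append(name)
    return tuple(names)
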