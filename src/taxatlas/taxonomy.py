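"""Rooted taxonomy shared by the k-mer classifier and cluster annotation.

The taxonomy is a rooted tree of nodes ``taxid -> (parent, rank, name)`` in the
style of the NCBI/GTDB dumps: exactly one root (its own parent), parent chains
that terminate at the root, and ranks that never increase toward the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

# canonical rank order, root-most first
RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species", "strain")
_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyDB:
    """Rooted taxonomy tree with LCA and rank-lifting queries."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.taxid: n for n in nodes}
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.rank not in _RANK_LEVEL:
                raise ValueError(f"unknown rank {node.rank!r} for taxid {node.taxid}")
            if node.parent not in self.nodes:
                raise ValueError(f"parent {node.parent} of taxid {node.taxid} missing")
        # validate acyclicity / rank monotonicity by walking every lineage
        for taxid in self.nodes:
            lineage = self.lineage(taxid)
            levels = [_RANK_LEVEL[self.nodes[t].rank] for t in lineage]
            if any(a >= b for a, b in zip(levels, levels[1:])):
                raise ValueError(f"ranks do not increase away from root for taxid {taxid}")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node path of taxids (root first)."""
        path = []
        seen = set()
        while True:
            if taxid in seen:
                raise ValueError("cycle in taxonomy")
            seen.add(taxid)
            path.append(taxid)
            parent = self.nodes[taxid].parent
            if parent == taxid:
                break
            taxid = parent
        return path[::-1]

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor of two taxids."""
        la, lb = self.lineage(a), self.lineage(b)
        lca = self.root
        for x, y in zip(la, lb):
            if x != y:
                break
            lca = x
        return lca

    def lca_many(self, taxids: Iterable[int]) -> int:
        it = iter(taxids)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca of empty set")
        for t in it:
            if t != acc:
                acc = self.lca(acc, t)
        return acc

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor (or self) at exactly ``rank``; None if the lineage has none
        (i.e. the node sits above that rank)."""
        if rank not in _RANK_LEVEL:
            raise ValueError(f"unknown rank {rank!r}")
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    def is_at_or_below(self, taxid: int, rank: str) -> bool:
        return _RANK_LEVEL[self.nodes[taxid].rank] >= _RANK_LEVEL[rank]

    # ---- serialization: single 4-column TSV (taxid, parent, rank, name) ----

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxid\tparent_taxid\trank\tname\n")
            for node in sorted(self.nodes.values(), key=lambda n: n.taxid):
                fh.write(f"{node.taxid}\t{node.parent}\t{node.rank}\t{node.name}\n")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyDB":
        nodes = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("taxid"):
                raise ValueError("taxonomy TSV must start with a 'taxid' header line")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"malformed taxonomy line {lineno}: {line!r}")
                taxid, parent, rank, name = fields
                nodes.append(TaxNode(int(taxid), int(parent), rank, name))
        return cls(nodes)


def linear_taxonomy(species: dict[int, str], genus_of: dict[int, int] | None = None,
                    genus_names: dict[int, str] | None = None) -> TaxonomyDB:
    """Convenience builder: root(1) -> genus -> species.

    ``species`` maps species taxid -> name. ``genus_of`` maps species taxid ->
    genus taxid; by default each species gets its own genus (taxid + 1000).
    """
    nodes = [TaxNode(1, 1, "root", "root")]
    if genus_of is None:
        genus_of = {t: t + 1000 for t in species}
    genus_names = genus_names or {}
    for g in sorted(set(genus_of.values())):
        nodes.append(TaxNode(g, 1, "genus", genus_names.get(g, f"genus_{g}")))
    for t, name in species.items():
        nodes.append(TaxNode(t, genus_of[t], "species", name))
    return TaxonomyDB(nodes)
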