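"""Rooted taxonomy: ancestry walks, rank resolution, and lowest common ancestor.

The tree is the structure every cluster label is computed on: after the
two-level hit filtering, surviving subject taxa are collapsed to their LCA
and that node becomes the cluster's (and its reads') label.
"""

from __future__ import annotations

from collections.abc import Iterable

from .model import TaxNode


class TaxonomyError(ValueError):
    pass


class TaxonomyTree:
    """Map of taxid -> TaxNode with exactly one self-parented root.

    Construction validates that every parent chain terminates at the root,
    so `ancestors` and `lca` never loop.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one self-parented root, found {len(roots)}"
            )
        self.root: int = roots[0]

        orphans = sorted(
            n.taxid
            for n in self.nodes.values()
            if n.parent not in self.nodes
        )
        if orphans:
            raise TaxonomyError(f"orphan nodes (parent missing): {orphans}")
        # depth check doubles as cycle detection
        self._depth: dict[int, int] = {self.root: 0}
        for taxid in self.nodes:
            self._resolve_depth(taxid)

    def _resolve_depth(self, taxid: int) -> int:
        path = []
        t = taxid
        while t not in self._depth:
            path.append(t)
            t = self.nodes[t].parent
            if len(path) > len(self.nodes):
                raise TaxonomyError(f"cycle detected through taxid {taxid}")
        d = self._depth[t]
        for p in reversed(path):
            d += 1
            self._depth[p] = d
        return self._depth[taxid]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def depth(self, taxid: int) -> int:
        self._require(taxid)
        return self._depth[taxid]

    def name(self, taxid: int) -> str:
        self._require(taxid)
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        self._require(taxid)
        return self.nodes[taxid].rank

    def _require(self, taxid: int) -> None:
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")

    def ancestors(self, taxid: int) -> list[int]:
        """Lineage from the node itself up to the root (inclusive)."""
        self._require(taxid)
        out = [taxid]
        t = taxid
        while t != self.root:
            t = self.nodes[t].parent
            out.append(t)
        return out

    def _lca_pair(self, a: int, b: int) -> int:
        # equalise depths, then walk both lineages up in lockstep
        while self._depth[a] > self._depth[b]:
            a = self.nodes[a].parent
        while self._depth[b] > self._depth[a]:
            b = self.nodes[b].parent
        while a != b:
            a = self.nodes[a].parent
            b = self.nodes[b].parent
        return a

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node that is ancestor-or-self of every input taxid."""
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("lca of an empty set is undefined")
        for t in taxids:
            self._require(t)
        result = taxids[0]
        for t in taxids[1:]:
            result = self._lca_pair(result, t)
        return result

    def rank_at_or_above(self, taxid: int, level: str) -> int | None:
        """Ancestor-or-self of ``taxid`` with rank ``level``, or None.

        Lineages that skip the rank (the NCBI-dump "no rank" gaps, or a query
        node already above the rank) resolve to None rather than a nearest
        neighbour, which keeps level-wise metric counting strict.
        """
        known = {self.nodes[t].rank for t in self.nodes}
        if level not in known:
            raise TaxonomyError(f"unknown rank {level!r}")
        for t in self.ancestors(taxid):
            if self.nodes[t].rank == level:
                return t
        return None
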