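"""Rooted species tree with stable integer edge numbering.

Every non-root node owns the edge joining it to its parent.  Edges are
numbered in depth-first post-order (children in input order), which is
deterministic across runs for a given Newick string.  A virtual *root stem*
edge (id one past the largest real edge id) represents "before the first
split" for event-dating bounds; it is not counted among the tree's edges.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = ["SpeciesTree", "read_newick_tree"]


class _Node:
    __slots__ = ("label", "parent", "children", "edge_id", "length")

    def __init__(self, label: Optional[str], length: float) -> None:
        self.label = label
        self.parent: Optional[_Node] = None
        self.children: list[_Node] = []
        self.edge_id: Optional[int] = None
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.label or self.clade_key()}>"

    def clade_key(self) -> str:
        return "+".join(sorted(self.leaf_labels()))

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaf_labels())
        return out


class SpeciesTree:
    """A rooted species tree supporting LCA, paths, and edge numbering."""

    def __init__(self, newick: str) -> None:
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf label in tree: {exc}") from exc
        seed = dt.seed_node
        if len(seed.child_nodes()) > 2:
            raise ValueError(
                "tree root is multifurcating; root the tree (binary root) first"
            )
        self.root = self._convert(seed)
        self._leaves: dict[str, _Node] = {}
        for node in self.postorder():
            if node.is_leaf():
                if node.label is None:
                    raise ValueError("leaf without a label")
                if node.label in self._leaves:
                    raise ValueError(f"duplicate leaf label {node.label!r}")
                self._leaves[node.label] = node
        self._edges: list[_Node] = []
        for node in self.postorder():
            if node is not self.root:
                node.edge_id = len(self._edges)
                self._edges.append(node)
        self.root_stem_edge = len(self._edges)

    @staticmethod
    def _convert(dnode) -> _Node:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = _Node(label, float(length))
        for ch in dnode.child_nodes():
            child = SpeciesTree._convert(ch)
            child.parent = node
            node.children.append(child)
        return node

    # -- basic queries ------------------------------------------------------

    def postorder(self, node: Optional[_Node] = None) -> Iterable[_Node]:
        node = node or self.root
        for ch in node.children:
            yield from self.postorder(ch)
        yield node

    @property
    def species(self) -> list[str]:
        return sorted(self._leaves)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def leaf(self, name: str) -> _Node:
        try:
            return self._leaves[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in tree") from None

    def edge_node(self, edge_id: int) -> _Node:
        """The node below the given edge (the edge joins it to its parent)."""
        return self._edges[edge_id]

    def ancestors(self, node: _Node) -> list[_Node]:
        """Node itself followed by its ancestors up to the root."""
        chain = [node]
        while chain[-1].parent is not None:
            chain.append(chain[-1].parent)
        return chain

    def lca(self, names: Sequence[str]) -> _Node:
        if not names:
            raise ValueError("LCA of an empty species set")
        chains = [self.ancestors(self.leaf(n)) for n in set(names)]
        common = set(id(x) for x in chains[0])
        for chain in chains[1:]:
            common &= set(id(x) for x in chain)
        for node in chains[0]:
            if id(node) in common:
                return node
        raise AssertionError("rooted tree must have an LCA")  # pragma: no cover

    def is_ancestor(self, anc: _Node, node: _Node) -> bool:
        """True iff ``anc`` is ``node`` or an ancestor of it."""
        return any(x is anc for x in self.ancestors(node))

    def leaf_distance(self, a: str, b: str) -> int:
        """Number of edges on the path between two leaves (topology only)."""
        na, nb = self.leaf(a), self.leaf(b)
        anc = self.lca([a, b])
        da = self.ancestors(na).index(anc)
        db = self.ancestors(nb).index(anc)
        return da + db

    # -- edge-path helpers for event dating ----------------------------------

    def edge_chain_to_root(self, edge_id: int) -> list[int]:
        """Edge ids from the given edge up to and including the root stem."""
        node = self.edge_node(edge_id)
        chain = []
        while node is not None and node is not self.root:
            chain.append(node.edge_id)
            node = node.parent
        chain.append(self.root_stem_edge)
        return chain

    def edge_path(self, upper: int, lower: int) -> Optional[list[int]]:
        """Edges from ``upper`` (ancestral) down to ``lower``, or None.

        None signals that ``upper`` is not on the rootward chain of
        ``lower`` (inconsistent bounds).
        """
        chain = self.edge_chain_to_root(lower)
        if upper not in chain:
            return None
        return list(reversed(chain[: chain.index(upper) + 1]))

    # -- export ---------------------------------------------------------------

    def annotated_newick(self) -> str:
        """Newick string with edge ids appended to labels as ``#<id>``."""

        def fmt(node: _Node) -> str:
            tag = "" if node.edge_id is None else f"#{node.edge_id}"
            if node.is_leaf():
                return f"{node.label}{tag}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = node.label or ""
            return f"({inner}){label}{tag}"

        return fmt(self.root) + ";"


def read_newick_tree(path) -> SpeciesTree:
    """Read a rooted Newick species tree from a file."""
    return SpeciesTree(Path(path).read_text())
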