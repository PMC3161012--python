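"""Placing conversion events on the species tree.

Each detecting outgroup bounds an event from above (the conversion postdates
the primary/outgroup split; the closest detecting outgroup gives the tightest
bound), and the set of primaries carrying the event bounds it from below
(the conversion predates their split).  The result is a sub-lineage — a
path of tree edges — or the conflict marker "?" when the bounds are
inconsistent.  Absence of detection in a species never tightens a bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .grouping import ConversionEvent
from .tree import SpeciesTree

__all__ = ["BranchPath", "upper_bound_edge", "lower_bound_edge", "assign_branch"]

CONFLICT = "?"


@dataclass(frozen=True)
class BranchPath:
    """Edge ids from earliest-possible to latest-possible, or conflict."""

    edges: Optional[tuple[int, ...]] = None

    @property
    def is_conflict(self) -> bool:
        return self.edges is None

    def __str__(self) -> str:
        if self.edges is None:
            return CONFLICT
        return "-".join(str(e) for e in self.edges)


def _edge_below_split(tree: SpeciesTree, primary: str, outgroup: str) -> int:
    """The edge on the primary's ancestry just below LCA(primary, outgroup)."""
    chain = tree.ancestors(tree.leaf(primary))
    split = tree.lca([primary, outgroup])
    idx = next(i for i, node in enumerate(chain) if node is split)
    return chain[idx - 1].edge_id


def upper_bound_edge(event: ConversionEvent, tree: SpeciesTree) -> Optional[int]:
    """Earliest possible edge of the event, from detecting outgroups.

    Per primary, the closest detecting outgroup (fewest edges on the
    leaf-to-leaf path) bounds the event below that split.  Across primaries
    the most recent of these edges that is still ancestral to (or is the
    terminal edge of) every carrying primary is returned; None when no
    candidate qualifies (an inconsistency resolved as "?" downstream).
    """
    primaries = sorted(event.primaries)
    candidates = []
    for primary, outgroups in sorted(event.outgroups_by_primary.items()):
        if not outgroups:
            continue
        closest = min(sorted(outgroups), key=lambda o: tree.leaf_distance(primary, o))
        candidates.append(_edge_below_split(tree, primary, closest))
    if not candidates:
        return None

    def ancestral_to_all(edge_id: int) -> bool:
        node = tree.edge_node(edge_id)
        return all(tree.is_ancestor(node, tree.leaf(p)) for p in primaries)

    valid = [e for e in candidates if ancestral_to_all(e)]
    if not valid:
        return None
    # "most recent" = deepest = longest chain to root
    return max(valid, key=lambda e: len(tree.edge_chain_to_root(e)))


def lower_bound_edge(event: ConversionEvent, tree: SpeciesTree) -> int:
    """Latest possible edge: above the LCA of all carrying primaries.

    A single primary bounds the event by its terminal edge.  When every leaf
    carries the event the LCA is the root and the virtual root-stem edge is
    returned.
    """
    primaries = sorted(event.primaries)
    if len(primaries) == 1:
        return tree.leaf(primaries[0]).edge_id
    lca = tree.lca(primaries)
    if lca is tree.root:
        return tree.root_stem_edge
    return lca.edge_id


def assign_branch(event: ConversionEvent, tree: SpeciesTree) -> BranchPath:
    """Sub-lineage between the bounds, or "?" on inconsistency."""
    lower = lower_bound_edge(event, tree)
    upper = upper_bound_edge(event, tree)
    if upper is None:
        return BranchPath(None)
    if lower == tree.root_stem_edge:
        chain = [tree.root_stem_edge]
    else:
        chain = tree.edge_chain_to_root(lower)
    if upper not in chain:
        return BranchPath(None)
    path = list(reversed(chain[: chain.index(upper) + 1]))
    return BranchPath(tuple(path))


def assign_branches(events, tree: SpeciesTree) -> None:
    """Stamp the branch column onto every event in place."""
    for event in events:
        event.branch = str(assign_branch(event, tree))
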