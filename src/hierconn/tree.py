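"""Rooted cluster hierarchies over node indices.

A :class:`ClusterTree` records the result of recursive partitioning: the root
holds every node index, each internal cluster's children partition it, and
the *tier* of a cluster is its depth below the root (root = tier 0). The tree
distance between two clusters drawn from the same tier is the number of tiers
one must ascend before they share an ancestor: 0 for the same cluster, 1 for
siblings, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


@dataclass
class ClusterNode:
    """One cluster: an ordered tuple of node indices plus its subclusters."""

    members: tuple[int, ...]
    tier: int
    children: list["ClusterNode"] = field(default_factory=list)
    parent: Optional["ClusterNode"] = None
    quality: object = None  # QualityCurve for clusters that were split

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, members: Sequence[int]) -> "ClusterNode":
        child = ClusterNode(tuple(members), self.tier + 1, parent=self)
        self.children.append(child)
        return child

    def __iter__(self) -> Iterator["ClusterNode"]:
        yield self
        for child in self.children:
            yield from child


@dataclass
class ClusterTree:
    """Rooted hierarchy of node-index clusters."""

    root: ClusterNode

    @property
    def n_nodes(self) -> int:
        return len(self.root.members)

    @property
    def depth(self) -> int:
        return max(node.tier for node in self.root)

    def nodes(self) -> Iterator[ClusterNode]:
        return iter(self.root)

    def clusters_at(self, tier: int) -> list[ClusterNode]:
        """Clusters whose own tier equals ``tier`` (exact-depth slice)."""
        return [node for node in self.root if node.tier == tier]

    def partition_at(self, tier: int) -> list[ClusterNode]:
        """The partition of all nodes obtained by cutting the tree at ``tier``.

        Branches that stopped early contribute their deepest cluster, so the
        result always partitions the root's members.
        """
        if tier < 0:
            raise ValueError("tier must be non-negative")
        out: list[ClusterNode] = []

        def descend(node: ClusterNode) -> None:
            if node.tier == tier or node.is_leaf():
                out.append(node)
                return
            for child in node.children:
                descend(child)

        descend(self.root)
        return out

    def distance(self, x: ClusterNode, y: ClusterNode, tier: int | None = None) -> int:
        """Tree distance between two clusters taken from the same tier.

        ``tier`` defaults to the deeper of the two clusters' tiers; clusters
        promoted from an early-stopped branch are measured at the requested
        tier, so sibling relationships stay consistent across the partition.
        """
        if x is y:
            return 0
        if tier is None:
            if x.tier != y.tier:
                raise ValueError(
                    f"clusters are at different tiers ({x.tier} vs {y.tier}); "
                    "pass an explicit tier"
                )
            tier = x.tier
        lca = self._lca(x, y)
        if lca is None:
            raise ValueError("clusters do not belong to the same tree")
        return tier - lca.tier

    @staticmethod
    def _lca(x: ClusterNode, y: ClusterNode) -> Optional[ClusterNode]:
        ancestors = set()
        node: Optional[ClusterNode] = x
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        node = y
        while node is not None:
            if id(node) in ancestors:
                return node
            node = node.parent
        return None

    def validate(self) -> None:
        """Check that every internal cluster's children partition it."""
        for node in self.root:
            if node.is_leaf():
                continue
            merged: list[int] = []
            for child in node.children:
                if child.parent is not node or child.tier != node.tier + 1:
                    raise ValueError("inconsistent parent/tier links")
                merged.extend(child.members)
            if sorted(merged) != sorted(node.members):
                raise ValueError(
                    f"children of cluster at tier {node.tier} do not partition it"
                )


def balanced_bisection_tree(n_nodes: int, depth: int) -> ClusterTree:
    """Balanced recursive bisection of ``0..n_nodes-1`` to ``depth`` tiers.

    Odd splits put the extra node in the left child.
    """
    if n_nodes < 2**depth:
        raise ValueError(
            f"n_nodes={n_nodes} cannot fill 2^{depth} leaf clusters"
        )
    root = ClusterNode(tuple(range(n_nodes)), 0)

    def split(node: ClusterNode) -> None:
        if node.tier == depth:
            return
        members = node.members
        half = (len(members) + 1) // 2  # remainder goes left
        for part in (members[:half], members[half:]):
            split(node.add_child(part))

    split(root)
    return ClusterTree(root)
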