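"""The partition tree over taxon subsets and its Newick serialization.

Every node corresponds to a non-empty set of taxa; the children of each
internal node partition it, the root is the full set, the leaves are
singletons.  A candidate set can be inserted only if it is *compatible* —
a subset of, superset of, or disjoint from every node set already present
(set equality is rejected).  Insertion reparents the absorbed children, so
the partition invariant is preserved by construction.

The rooted tree doubles as the standard encoding of an unrooted topology:
a root with three or more children is the usual unrooted multifurcation,
and a root with exactly two children encodes the same unrooted tree as the
edge between them.  No re-rooting is performed and no branch lengths exist.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = ["PartitionNode", "PartitionTree", "init_star"]

_NEWICK_META = re.compile(r"[\s()\[\]:;,'\"]")


@dataclass(eq=False)
class PartitionNode:
    taxa: frozenset[int]
    parent: Optional["PartitionNode"] = None
    children: list["PartitionNode"] = field(default_factory=list)
    final: bool = False

    @property
    def is_leaf(self) -> bool:
        return len(self.taxa) == 1

    def path_to_root(self) -> list["PartitionNode"]:
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out


class PartitionTree:
    """Rooted multifurcating tree of taxon subsets (colors 1..l)."""

    def __init__(self, taxa: list[str]):
        ell = len(taxa)
        if ell < 2:
            raise ValueError("a partition tree needs at least two taxa")
        self.taxa = list(taxa)
        self.root = PartitionNode(taxa=frozenset(range(1, ell + 1)))
        self.leaves: dict[int, PartitionNode] = {}
        for color in range(1, ell + 1):
            leaf = PartitionNode(taxa=frozenset([color]), parent=self.root, final=True)
            self.root.children.append(leaf)
            self.leaves[color] = leaf

    # -- queries ---------------------------------------------------------

    def nodes(self) -> Iterable[PartitionNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def node_sets(self) -> set[frozenset[int]]:
        return {n.taxa for n in self.nodes()}

    def check_partition_invariant(self) -> None:
        for node in self.nodes():
            if node.children:
                union: set[int] = set()
                for c in node.children:
                    if union & c.taxa:
                        raise AssertionError("children overlap")
                    union |= c.taxa
                if union != set(node.taxa):
                    raise AssertionError("children do not cover their parent")

    def is_compatible(
        self, candidate: frozenset[int]
    ) -> tuple[bool, Optional[PartitionNode], list[PartitionNode]]:
        """Test insertability of a candidate set; O(l).

        Walks the leaf-to-root path from one member to the smallest node P
        whose set strictly contains the candidate, then verifies that the
        children of P contained in the candidate union exactly to it.  On
        success returns (True, P, absorbed children).
        """
        candidate = frozenset(candidate)
        if not candidate or not candidate <= self.root.taxa:
            return False, None, []
        any_member = next(iter(candidate))
        parent = None
        for node in self.leaves[any_member].path_to_root():
            if node.taxa == candidate:
                return False, None, []  # equality is incompatible
            if candidate < node.taxa:
                parent = node
                break
        if parent is None:
            return False, None, []
        absorbed = [c for c in parent.children if c.taxa <= candidate]
        covered: set[int] = set()
        for c in absorbed:
            covered |= c.taxa
        if covered != set(candidate):
            return False, None, []  # partial overlap with some child
        return True, parent, absorbed

    # -- mutation --------------------------------------------------------

    def add_node(self, candidate: frozenset[int]) -> PartitionNode:
        """Insert a compatible set; absorbed siblings become its children."""
        ok, parent, absorbed = self.is_compatible(candidate)
        if not ok:
            raise ValueError(f"set {sorted(candidate)} is incompatible with the tree")
        node = PartitionNode(taxa=frozenset(candidate), parent=parent)
        for c in absorbed:
            parent.children.remove(c)
            c.parent = node
            node.children.append(c)
        parent.children.append(node)
        if len(node.children) == 2:
            node.final = True
        self.check_partition_invariant()
        return node

    def remove_node(self, node: PartitionNode) -> None:
        """Inverse of add_node (test support): splice the node out."""
        if node.parent is None:
            raise ValueError("cannot remove the root")
        parent = node.parent
        parent.children.remove(node)
        for c in node.children:
            c.parent = parent
            parent.children.append(c)
        self.check_partition_invariant()

    # -- output ----------------------------------------------------------

    def _name(self, color: int) -> str:
        return _NEWICK_META.sub("_", self.taxa[color - 1])

    def to_newick(self) -> str:
        """Serialize with taxon names at leaves, no branch lengths;
        deterministic child order (by smallest member color)."""

        def render(node: PartitionNode) -> str:
            if node.is_leaf:
                return self._name(next(iter(node.taxa)))
            kids = sorted(node.children, key=lambda c: min(c.taxa))
            return "(" + ",".join(render(k) for k in kids) + ")"

        return render(self.root) + ";"


def init_star(taxa: list[str]) -> PartitionTree:
    """Rooted star: non-final root over all taxa, final singleton leaves."""
    return PartitionTree(taxa)
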