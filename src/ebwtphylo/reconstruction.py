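"""The reconstruction driver: iterate refinement over a queue of open nodes.

Start from the rooted star over all taxa.  Repeatedly dequeue a non-final
node X, refine the family formed by its current children on the index
restricted to X's colors, and insert the returned compatible subsets.
A node is final when it has at most two children or when refinement yields
nothing; the loop ends at quiescence, after at most O(l) refinement calls.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .ebwt import EbwtIndex
from .partition_tree import PartitionNode, PartitionTree, init_star
from .refinement import (
    SelectionPolicy,
    SiblingFamily,
    score_subsets,
    select_compatible,
)

__all__ = ["reconstruct", "draw_and_mark", "IterationRecord"]


@dataclass
class IterationRecord:
    """Structured log of one refinement iteration."""

    node: tuple[int, ...]
    h: int
    table_size: int
    n_selected: int
    selected: list[tuple[int, ...]]
    marked_final: bool


def draw_and_mark(
    tree: PartitionTree,
    node: PartitionNode,
    L: list[frozenset[int]],
    queue: deque[PartitionNode],
) -> None:
    """Apply a refinement outcome to the tree and the work queue.

    Empty L finalizes the node.  Otherwise every set of L is inserted (they
    are compatible by the refinement contract); afterwards each new node and
    the refined node itself is finalized if it holds at most two children,
    or (re-)enqueued for further refinement.
    """
    if not L:
        node.final = True
        return
    new_nodes = []
    for candidate in L:
        new_nodes.append(tree.add_node(candidate))
    for affected in new_nodes + [node]:
        if len(affected.children) <= 2:
            affected.final = True
        else:
            affected.final = False
            if affected not in queue:
                queue.append(affected)


def reconstruct(
    index: EbwtIndex,
    k_m: int,
    tau: float,
    policy: SelectionPolicy | None = None,
    trace: list[IterationRecord] | None = None,
) -> PartitionTree:
    """Run the full reconstruction on a prebuilt index.

    The index must cover all taxa; ``k_m`` is the minimum context length and
    ``tau`` the support threshold in (0, 1].  An optional ``trace`` list
    collects one :class:`IterationRecord` per refinement call.
    """
    if k_m < 1:
        raise ValueError("k_m must be >= 1")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    tree = init_star(index.taxa)
    ell = len(index.taxa)
    if len(tree.root.children) <= 2:
        tree.root.final = True
        return tree

    queue: deque[PartitionNode] = deque([tree.root])
    max_insertions = max(ell - 2, 0)
    inserted = 0
    iterations = 0
    iteration_cap = 4 * ell + 4  # safety net; quiescence arrives well before

    while queue:
        iterations += 1
        if iterations > iteration_cap:
            raise RuntimeError("refinement loop failed to reach quiescence")
        node = queue.popleft()
        if node.final:
            continue
        if len(node.children) <= 2:
            node.final = True
            continue
        family = SiblingFamily(
            elements=[c.taxa for c in node.children], tau=tau
        )
        table = score_subsets(index, family, k_m)
        L = select_compatible(table, family, policy)
        inserted += len(L)
        if inserted > max_insertions:
            raise AssertionError("more insertions than a partition tree admits")
        draw_and_mark(tree, node, L, queue)
        if trace is not None:
            trace.append(
                IterationRecord(
                    node=tuple(sorted(node.taxa)),
                    h=family.h,
                    table_size=len(table),
                    n_selected=len(L),
                    selected=[tuple(sorted(u)) for u in L],
                    marked_final=node.final,
                )
            )
    return tree
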