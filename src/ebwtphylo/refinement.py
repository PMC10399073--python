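"""Refinement of a sibling family: score gamma-subsets, select compatible unions.

Given the children C_1..C_h of a partition-tree node, the refinement pass
restricts the index to X = union(C_k), walks every positional cluster once,
and keeps the *relevant* ones — clusters whose eBWT slice is not a
single-symbol run, whose gamma-coloring touches more than one but fewer than
all h elements, and whose every touched element is supported by at least a
fraction tau of its distinct colors.  Each relevant cluster votes (+1) for
its gamma-subset; the highest-scoring subsets whose unions are mutually
compatible become the new internal nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import PositionalCluster, enumerate_clusters
from .ebwt import EbwtIndex, restrict

__all__ = [
    "SiblingFamily",
    "GammaColoring",
    "ScoreTable",
    "SelectionPolicy",
    "gamma_coloring",
    "is_relevant",
    "score_subsets",
    "select_compatible",
    "refine",
]


@dataclass
class SiblingFamily:
    """The h disjoint color sets C_1..C_h under refinement, plus tau.

    ``chi`` maps each color to the (0-based) index of the element owning it;
    colors outside X = union(C_k) are absent from the mapping.
    """

    elements: list[frozenset[int]]
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        self.elements = [frozenset(e) for e in self.elements]
        if any(not e for e in self.elements):
            raise ValueError("sibling sets must be non-empty")
        union: set[int] = set()
        for e in self.elements:
            if union & e:
                raise ValueError("sibling sets must be pairwise disjoint")
            union |= e
        self.X: frozenset[int] = frozenset(union)
        self.chi: dict[int, int] = {
            r: k for k, e in enumerate(self.elements) for r in e
        }

    @property
    def h(self) -> int:
        return len(self.elements)

    def sizes(self) -> np.ndarray:
        return np.array([len(e) for e in self.elements], dtype=np.int64)


@dataclass(frozen=True)
class GammaColoring:
    """Elements of the family appearing in a cluster's cda slice, with the
    number of DISTINCT colors of each appearing element."""

    members: frozenset[int]  # 0-based element indices
    support: Mapping[int, int]


class ScoreTable(dict):
    """Mapping canonical gamma-subset (sorted tuple of element indices) ->
    number of relevant clusters that voted for it."""

    def vote(self, members: Iterable[int]) -> None:
        key = tuple(sorted(members))
        self[key] = self.get(key, 0) + 1


@dataclass
class SelectionPolicy:
    """Stop rules of the greedy selection.

    max_parts      cap on |L| (default h-2, the most a family can yield)
    score_drop_ratio  stop when score < highest / ratio
    failure_cap    consecutive failed insertions allowed (default min{2h, 100})
    """

    score_drop_ratio: float = 100.0
    max_parts: int | None = None
    failure_cap: int | None = None

    def resolved(self, h: int) -> tuple[int, float, int]:
        max_parts = self.max_parts if self.max_parts is not None else max(h - 2, 0)
        cap = self.failure_cap if self.failure_cap is not None else min(2 * h, 100)
        if self.score_drop_ratio <= 1:
            raise ValueError("score_drop_ratio must exceed 1")
        return max_parts, self.score_drop_ratio, max(cap, 1)


def gamma_coloring(family: SiblingFamily, cda_slice: np.ndarray) -> GammaColoring:
    """Gamma-coloring of a cda slice: which elements appear, how supported."""
    distinct = np.unique(np.asarray(cda_slice))
    support: dict[int, int] = {}
    for c in distinct:
        k = family.chi.get(int(c))
        if k is not None:
            support[k] = support.get(k, 0) + 1
    return GammaColoring(members=frozenset(support), support=support)


def is_relevant(
    cluster: PositionalCluster,
    ebwt_slice: np.ndarray,
    coloring: GammaColoring,
    family: SiblingFamily,
) -> bool:
    """Relevance test: (i) the eBWT slice is not a one-symbol run (all
    end-markers count as one symbol class); (ii) the coloring has between 2
    and h-1 members; (iii) every member k has at least tau*|C_k| of its
    distinct colors in the slice (real-valued comparison)."""
    s = np.asarray(ebwt_slice)
    if len(np.unique(s)) < 2:
        return False
    card = len(coloring.members)
    if not 1 < card < family.h:
        return False
    for k in coloring.members:
        if coloring.support[k] < family.tau * len(family.elements[k]):
            return False
    return True


def _score_vectorized(
    sub: EbwtIndex, family: SiblingFamily, k_m: int
) -> ScoreTable:
    """One streaming pass over the restricted index: enumerate clusters and
    accumulate votes of the relevant ones, all in flat array arithmetic."""
    table = ScoreTable()
    clusters = enumerate_clusters(sub, k_m)
    if not clusters:
        return table
    h = family.h
    starts = np.array([c.i - 1 for c in clusters], dtype=np.int64)  # 0-based
    ends = np.array([c.j for c in clusters], dtype=np.int64)  # exclusive
    lens = ends - starts
    nseg = len(clusters)

    # condition (i): a boundary between unequal adjacent symbols inside the slice
    diff = np.concatenate(([0], (sub.ebwt[1:] != sub.ebwt[:-1]).astype(np.int64)))
    cdiff = np.cumsum(diff)
    not_run = (cdiff[ends - 1] - cdiff[starts]) > 0

    # flatten all in-cluster positions
    seg_id = np.repeat(np.arange(nseg), lens)
    offs = np.arange(len(seg_id)) - np.repeat(np.cumsum(lens) - lens, lens)
    pos = np.repeat(starts, lens) + offs

    # distinct-color support per (segment, element): count positions whose
    # color did not occur earlier in the same segment
    colors = sub.cda[pos].astype(np.int64)
    order = np.lexsort((pos, colors, seg_id))
    sid_o, col_o = seg_id[order], colors[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = (sid_o[1:] != sid_o[:-1]) | (col_o[1:] != col_o[:-1])

    elem_of_color = np.full(max(family.chi, default=0) + 1, -1, dtype=np.int64)
    for r, k in family.chi.items():
        elem_of_color[r] = k
    elem_o = elem_of_color[col_o]
    valid = first & (elem_o >= 0)

    support = np.zeros((nseg, h), dtype=np.int64)
    np.add.at(support, (sid_o[valid], elem_o[valid]), 1)

    members = support > 0
    card = members.sum(axis=1)
    thresh = family.tau * family.sizes()  # per element
    supported = ((support >= thresh) | ~members).all(axis=1)
    relevant = not_run & (card > 1) & (card < h) & supported

    for s in np.flatnonzero(relevant):
        table.vote(int(k) for k in np.flatnonzero(members[s]))
    return table


def score_subsets(index: EbwtIndex, family: SiblingFamily, k_m: int) -> ScoreTable:
    """Restrict the index to X = union(C_k), enumerate positional clusters at
    k_m, and tally one vote per relevant cluster for its gamma-subset."""
    if k_m < 1:
        raise ValueError("k_m must be >= 1")
    sub = restrict(index, family.X)
    return _score_vectorized(sub, family, k_m)


def _union(family: SiblingFamily, members: Sequence[int]) -> frozenset[int]:
    u: set[int] = set()
    for k in members:
        u |= family.elements[k]
    return frozenset(u)


def select_compatible(
    table: ScoreTable,
    family: SiblingFamily,
    policy: SelectionPolicy | None = None,
) -> list[frozenset[int]]:
    """Greedy selection of high-scoring, mutually compatible unions.

    Subsets are visited by score descending (ties: larger union first, then
    lexicographically smaller sorted color list).  A union U is accepted iff
    for every set A already in L it satisfies U subset A, U superset A, or
    U disjoint A, and U duplicates neither an element of L, nor a single
    C_k, nor X.  Selection stops at max_parts accepted sets, when the score
    falls below highest/score_drop_ratio, or after failure_cap consecutive
    rejections.
    """
    policy = policy or SelectionPolicy()
    max_parts, drop_ratio, failure_cap = policy.resolved(family.h)
    if not table or max_parts == 0:
        return []

    def sort_key(item: tuple[tuple[int, ...], int]):
        members, score = item
        u = sorted(_union(family, members))
        return (-score, -len(u), u)

    ranked = sorted(table.items(), key=sort_key)
    highest = ranked[0][1]
    forbidden = {frozenset(e) for e in family.elements}
    forbidden.add(family.X)

    L: list[frozenset[int]] = []
    failures = 0
    for members, score in ranked:
        if len(L) >= max_parts:
            break
        if score < highest / drop_ratio:
            break
        U = _union(family, members)
        ok = U not in forbidden and U not in L
        if ok:
            for A in L:
                if not (U < A or A < U or not (U & A)):
                    ok = False
                    break
        if ok:
            L.append(U)
            failures = 0
        else:
            failures += 1
            if failures > failure_cap:
                break
    return L


def refine(
    index: EbwtIndex,
    family: SiblingFamily,
    k_m: int,
    policy: SelectionPolicy | None = None,
) -> list[frozenset[int]]:
    """Full refinement of one sibling family: score, then greedy-select.

    Every returned set is the union of >= 2 and <= h-1 elements of the
    family, hence a strict subset of X; the list is pairwise compatible and
    holds at most h-2 sets.
    """
    table = score_subsets(index, family, k_m)
    return select_compatible(table, family, policy)
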