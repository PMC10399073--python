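"""Local minima of the LCP array and eBWT positional clusters.

A positional cluster is a maximal run of lexicographically adjacent suffixes
that share a context of length at least k_m and contains no local minimum of
the LCP array: cluster boundaries are data-driven instead of being tied to a
fixed k-mer length.  The local-minimum definition is run-aware — within a run
of equal LCP values only the first index can qualify, and the value just past
the run must be strictly larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ebwt import EbwtIndex

__all__ = [
    "PositionalCluster",
    "local_minima",
    "enumerate_clusters",
    "cluster_context_length",
    "enumerate_lcp_intervals",
]


@dataclass(frozen=True)
class PositionalCluster:
    """Maximal suffix-rank interval [i, j] (1-based, inclusive, j > i) with
    internal lcp >= k_m and no internal local minimum; ``context_length`` is
    the length of the longest common prefix shared by suffixes i..j."""

    i: int
    j: int
    context_length: int


def local_minima(lcp: Sequence[int] | np.ndarray) -> list[int]:
    """Run-aware local minima of a 1-based LCP sequence.

    Position p (1 < p < M) is a minimum iff lcp[p-1] > lcp[p] and, with j the
    run length of the value lcp[p] starting at p, position p+j exists (p+j <=
    M) and lcp[p+j] > lcp[p].  Only the first position of a run can qualify.
    The input sequence is indexed 1-based: element t of the underlying array
    is lcp[t+1].
    """
    a = np.asarray(lcp, dtype=np.int64)
    M = len(a)
    if M < 1:
        raise ValueError("lcp sequence must be non-empty")
    if M < 3:
        return []
    run_starts = np.flatnonzero(np.concatenate(([True], a[1:] != a[:-1])))
    vals = a[run_starts]
    run_ends = np.concatenate((run_starts[1:], [M]))  # exclusive
    ok = np.zeros(len(run_starts), dtype=bool)
    ok[1:] = vals[:-1] > vals[1:]  # strictly falls into the run
    rises = np.zeros(len(run_starts), dtype=bool)
    rises[:-1] = vals[1:] > vals[:-1]  # strictly rises after the run
    ok &= rises & (run_ends < M)  # the element past the run must exist
    return [int(p) + 1 for p in run_starts[ok]]


def _connected_pairs(index: EbwtIndex, k_m: int) -> np.ndarray:
    """Boolean array over 1-based lcp indices 2..N: True where the suffix
    pair (r-1, r) shares a context of length >= k_m and r is not a local
    minimum; maximal True runs are exactly the positional clusters."""
    N = index.n
    minima = local_minima(index.lcp)  # over the full N+1-entry array
    is_min = np.zeros(N + 2, dtype=bool)
    if minima:
        is_min[np.asarray(minima, dtype=np.int64)] = True
    conn = np.zeros(N + 1, dtype=bool)  # conn[r] for r in 2..N
    r = np.arange(2, N + 1)
    conn[2:] = (index.lcp[1:N] >= k_m) & ~is_min[r]
    return conn


def _runs(conn: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of conn[2..]; a run over lcp indices r0..r1 joins
    suffixes r0-1 .. r1, returned as 1-based inclusive suffix intervals."""
    padded = np.concatenate(([False], conn, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)  # index into conn
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s) - 1, int(e)) for s, e in zip(starts, ends)]


def enumerate_clusters(index: EbwtIndex, k_m: int) -> list[PositionalCluster]:
    """Enumerate all eBWT positional clusters at minimum context length k_m.

    One linear scan: a position r with lcp[r] >= k_m joins suffixes r-1 and r
    unless r is a local minimum, in which case the previous cluster closes at
    r-1 and the next opens at r.  Single-suffix blocks are suppressed — a
    lone suffix can never witness a context shared between sibling groups.
    """
    if k_m < 1:
        raise ValueError("k_m must be >= 1")
    conn = _connected_pairs(index, k_m)
    out = []
    for i, j in _runs(conn):
        ctx = int(min(index.lcp[i], index.lcp[j - 1]))
        out.append(PositionalCluster(i=i, j=j, context_length=ctx))
    return out


def cluster_context_length(lcp: Sequence[int] | np.ndarray, i: int, j: int) -> int:
    """Shared-context length of a cluster [i, j]: min(lcp[i+1], lcp[j]).

    Inside a positional cluster the LCP values are non-decreasing then
    non-increasing, so the minimum over lcp[i+1..j] sits at one of the two
    ends.  ``lcp`` uses the stored convention (array element t is the 1-based
    lcp[t+1], as in :class:`EbwtIndex`).
    """
    if j <= i:
        raise ValueError("cluster must span at least two suffixes")
    a = np.asarray(lcp)
    return int(min(a[i], a[j - 1]))


def enumerate_lcp_intervals(index: EbwtIndex, k: int) -> list[tuple[int, int]]:
    """Maximal intervals [i, j] (j > i) with lcp[r] >= k for all i < r <= j.

    These are in one-to-one correspondence with the shared k-mers of the
    collection; positional clusters at k_m = k refine them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    N = index.n
    conn = np.zeros(N + 1, dtype=bool)
    conn[2:] = index.lcp[1:N] >= k
    return _runs(conn)
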