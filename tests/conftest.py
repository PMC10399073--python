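"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's construction path: the index
oracle materializes every decorated suffix and sorts it with bytewise
comparison; the cluster oracle tests every candidate interval against the
definitions literally.  They exist to pin the fast implementations down.
"""

from __future__ import annotations

import numpy as np
import pytest

from ebwtphylo import Collection, EbwtIndex, fig1_fixture, build_index


# --------------------------------------------------------------------------
# naive index oracle


def naive_index(collection: Collection) -> EbwtIndex:
    """Enumerate, decorate and sort all suffixes explicitly.

    Each symbol is encoded as two bytes so that plain bytes comparison
    realizes the order $_1 < ... < $_m < A < C < G < T with end-markers
    ordered by global string index and matching nothing (every marker code
    is unique).
    """
    strings = collection.strings
    m = len(strings)
    enc_parts = []
    owner_of = []
    for g, s in enumerate(strings):
        for ch in s:
            enc_parts.append(bytes([0x10, "ACGT".index(ch) + 1]))
        enc_parts.append(bytes([0x00]) + bytes([g + 1]))
        owner_of.extend([g] * (len(s) + 1))
    encoded = b"".join(enc_parts)
    N = len(encoded) // 2

    # suffixes never sort past their own end-marker: every marker is unique,
    # so bytewise comparison of the full tail is safe
    starts = []
    acc = 0
    for s in strings:
        starts.append(acc)
        acc += len(s) + 1
    order = sorted(range(N), key=lambda p: encoded[2 * p :])

    ebwt = bytearray()
    cda = []
    for p in order:
        g = owner_of[p]
        if p == starts[g]:
            ebwt.append(ord("#"))
        else:
            sym = encoded[2 * (p - 1) : 2 * p]
            ebwt.append(b"ACGT"[sym[1] - 1] if sym[0] == 0x10 else ord("#"))
        cda.append(collection.colors[g])

    lcp = [0] * (N + 1)
    for r in range(1, N):
        a = encoded[2 * order[r - 1] :]
        b = encoded[2 * order[r] :]
        k = 0
        while 2 * k + 1 < len(a) and 2 * k + 1 < len(b) and a[2 * k : 2 * k + 2] == b[2 * k : 2 * k + 2]:
            k += 1
        lcp[r] = k

    return EbwtIndex(
        ebwt=np.frombuffer(bytes(ebwt), dtype=np.uint8).copy(),
        lcp=np.array(lcp, dtype=np.int64),
        cda=np.array(cda, dtype=np.int32),
        taxa=list(collection.taxa),
    )


# --------------------------------------------------------------------------
# quadratic cluster oracle


def brute_force_minima(lcp) -> list[int]:
    """Literal run-aware local-minimum definition, 1-based positions."""
    a = list(lcp)
    M = len(a)
    out = []
    for p in range(2, M):  # 1-based, 1 < p < M
        if a[p - 2] <= a[p - 1]:
            continue
        j = 0
        while p + j <= M and a[p + j - 1] == a[p - 1]:
            j += 1
        if p + j <= M and a[p + j - 1] > a[p - 1]:
            out.append(p)
    return out


def brute_force_clusters(lcp, k_m: int) -> list[tuple[int, int]]:
    """Every maximal interval [i, j] (j > i) with internal lcp >= k_m and no
    internal local minimum, found by testing all candidates."""
    a = list(lcp)
    M = len(a)  # lcp positions 1..M; suffix ranks 1..M-1
    minima = set(brute_force_minima(a))

    def valid(i, j):
        return all(
            a[r - 1] >= k_m and r not in minima for r in range(i + 1, j + 1)
        )

    valid_intervals = [
        (i, j)
        for i in range(1, M)
        for j in range(i + 1, M)
        if valid(i, j)
    ]
    out = []
    for i, j in valid_intervals:
        if any(
            (i2 <= i and j <= j2) and (i2, j2) != (i, j)
            for i2, j2 in valid_intervals
        ):
            continue
        out.append((i, j))
    return sorted(out)


# --------------------------------------------------------------------------
# random collection generator


def random_collection(rng: np.random.Generator, max_taxa=6, max_strings=8,
                      max_len=50) -> Collection:
    ell = int(rng.integers(2, max_taxa + 1))
    colors, strings = [], []
    for color in range(1, ell + 1):
        for _ in range(int(rng.integers(1, max(2, max_strings // ell) + 1))):
            n = int(rng.integers(1, max_len + 1))
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))
            colors.append(color)
            strings.append(s)
    return Collection(
        taxa=[f"t{i}" for i in range(1, ell + 1)], colors=colors, strings=strings
    )


def indices_equal(a: EbwtIndex, b: EbwtIndex) -> bool:
    """Position-wise equality over ebwt/lcp/cda (end-markers as one class)."""
    return (
        np.array_equal(a.ebwt, b.ebwt)
        and np.array_equal(a.lcp, b.lcp)
        and np.array_equal(a.cda, b.cda)
    )


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def fig1_collection() -> Collection:
    return fig1_fixture()


@pytest.fixture(scope="session")
def fig1_index(fig1_collection) -> EbwtIndex:
    return build_index(fig1_collection)
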