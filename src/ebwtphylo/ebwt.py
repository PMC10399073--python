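"""eBWT / LCP / CDA construction, restriction, and on-disk round-tripping.

The substrate of the whole method: all suffixes of all strings (each string
terminated by its own end-marker) are sorted lexicographically under

    $_1 < $_2 < ... < $_m < A < C < G < T,

with end-markers ordered by global string index.  ``ebwt[i]`` is the symbol
circularly preceding suffix i (the string's own end-marker when the suffix
starts the string); ``lcp`` holds longest-common-prefix lengths between
lexicographically adjacent suffixes, where end-markers never match anything;
``cda`` maps each suffix to the color (taxon index) of the string owning it.

Conventions: public positions are 1-based with inclusive intervals [i, j],
mirroring the worked examples of the positional-clustering literature.  The
stored ``lcp`` array has N+1 entries; entry t (0-based) is the 1-based
lcp[t+1], so lcp[0] and lcp[N] are the zero sentinels.  End-markers in
``ebwt`` are all stored as the single class symbol ``#`` — their identity is
never needed downstream (they never extend a common prefix, and a cluster's
run test treats them as one symbol class).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import Collection

__all__ = [
    "EbwtIndex",
    "build_index",
    "restrict",
    "write_index",
    "read_index",
    "SENTINEL",
]

SENTINEL = ord("#")
_DIALECT_VERSION = 1

_LETTER_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_CODE_ASCII = np.zeros(5, dtype=np.uint8)
for _b, _c in _LETTER_CODE.items():
    _CODE_ASCII[_c] = ord(_b)


@dataclass
class EbwtIndex:
    """Parallel eBWT/LCP/CDA arrays over the N suffixes of a collection.

    ebwt : uint8[N]      ASCII 'A'/'C'/'G'/'T', end-markers as '#'
    lcp  : int64[N+1]    stored entry t == 1-based lcp[t+1]; both ends 0
    cda  : int32[N]      color (taxon index, 1..l) of the suffix's string
    da   : int32[N]|None optional 1-based global string index per suffix
    taxa : taxon names; colors refer to positions in this list
    """

    ebwt: np.ndarray
    lcp: np.ndarray
    cda: np.ndarray
    taxa: list[str]
    da: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.lcp) != len(self.ebwt) + 1:
            raise ValueError("lcp must have exactly one entry more than ebwt")
        if len(self.cda) != len(self.ebwt):
            raise ValueError("cda and ebwt must have equal length")
        if self.lcp[0] != 0 or self.lcp[-1] != 0:
            raise ValueError("lcp sentinels must be 0")

    @property
    def n(self) -> int:
        """Total number of suffixes N."""
        return len(self.ebwt)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def colors_present(self) -> set[int]:
        return set(int(c) for c in np.unique(self.cda))

    def lcp_at(self, p: int) -> int:
        """1-based lcp[p], p in 1..N+1."""
        if not 1 <= p <= self.n + 1:
            raise IndexError(p)
        return int(self.lcp[p - 1])

    def ebwt_slice(self, i: int, j: int) -> np.ndarray:
        """ebwt[i, j] for a 1-based inclusive interval."""
        return self.ebwt[i - 1 : j]

    def cda_slice(self, i: int, j: int) -> np.ndarray:
        """cda[i, j] for a 1-based inclusive interval."""
        return self.cda[i - 1 : j]


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort); O(n log^2 n).

    Every end-marker code is unique, so ranks separate quickly and suffix
    comparisons never cross an end-marker.
    """
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_o = rank[order]
        k_o = key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


try:  # pragma: no cover - exercised indirectly through build_index
    from numba import njit

    @njit(cache=False)
    def _kasai(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
        n = len(sa)
        rank = np.empty(n, dtype=np.int64)
        for i in range(n):
            rank[sa[i]] = i
        lcp = np.zeros(n, dtype=np.int64)
        h = 0
        for i in range(n):
            r = rank[i]
            if r > 0:
                j = sa[r - 1]
                while i + h < n and j + h < n and text[i + h] == text[j + h]:
                    h += 1
                lcp[r] = h
                if h > 0:
                    h -= 1
            else:
                h = 0
        return lcp

except ImportError:  # pragma: no cover

    def _kasai(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
        n = len(sa)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = np.arange(n)
        lcp = np.zeros(n, dtype=np.int64)
        h = 0
        for i in range(n):
            r = rank[i]
            if r > 0:
                j = sa[r - 1]
                while i + h < n and j + h < n and text[i + h] == text[j + h]:
                    h += 1
                lcp[r] = h
                if h > 0:
                    h -= 1
            else:
                h = 0
        return lcp


def build_index(collection: Collection, with_da: bool = False) -> EbwtIndex:
    """Build the eBWT, LCP and CDA for a collection by suffix sorting.

    Each string's suffixes carry the string's own distinct end-marker; the
    marker codes grow with the global string index, which realizes the
    declared end-marker order.  LCP values never count end-marker matches
    because every marker code occurs exactly once in the concatenation.
    """
    m = collection.n_strings
    if m == 0:
        raise ValueError("empty collection")
    lengths = np.array([len(s) for s in collection.strings], dtype=np.int64)
    starts = np.zeros(m, dtype=np.int64)
    np.cumsum(lengths[:-1] + 1, out=starts[1:])
    N = int(np.sum(lengths + 1))

    # integer codes: end-marker of global string g (1-based) -> g,
    # letters -> m + {A:1, C:2, G:3, T:4}
    text = np.empty(N, dtype=np.int64)
    letter_base = m
    lut = np.zeros(256, dtype=np.int64)
    for b, c in _LETTER_CODE.items():
        lut[ord(b)] = letter_base + c
    for g, s in enumerate(collection.strings):
        a = starts[g]
        text[a : a + len(s)] = lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        text[a + len(s)] = g + 1

    sa = _suffix_array(text)
    kasai = _kasai(text, sa)

    owner = np.searchsorted(starts, sa, side="right") - 1  # 0-based string idx
    is_start = sa == starts[owner]

    ebwt = np.empty(N, dtype=np.uint8)
    prev_codes = text[sa - 1]  # valid wherever not a string start
    letters = prev_codes - letter_base
    np.clip(letters, 0, 4, out=letters)
    ebwt[:] = _CODE_ASCII[letters]
    ebwt[is_start] = SENTINEL

    colors = np.asarray(collection.colors, dtype=np.int32)
    cda = colors[owner]

    lcp = np.zeros(N + 1, dtype=np.int64)
    lcp[:N] = kasai  # kasai[0] == 0; stored entry t is 1-based lcp[t+1]

    da = (owner + 1).astype(np.int32) if with_da else None
    return EbwtIndex(ebwt=ebwt, lcp=lcp, cda=cda, taxa=list(collection.taxa), da=da)


def restrict(index: EbwtIndex, keep: Iterable[int]) -> EbwtIndex:
    """Restrict the index to a subset of colors by one linear scan.

    The relative order of the kept suffixes is unchanged; the emitted lcp
    between consecutive kept positions p < q is min over the original
    lcp(p, q], because dropped suffixes in between can only shorten, never
    lengthen, the common prefix of the survivors.  Nothing is rebuilt.
    """
    keep_set = set(int(c) for c in keep)
    if not keep_set:
        raise ValueError("keep must be non-empty")
    present = index.colors_present()
    if not keep_set & present:
        raise ValueError("no suffix carries a color in the keep set")
    if present <= keep_set:
        return index  # identity restriction

    keep_arr = np.zeros(index.n_taxa + 1, dtype=bool)
    keep_arr[sorted(keep_set & present)] = True
    mask = keep_arr[index.cda]
    idx = np.flatnonzero(mask)  # 0-based kept suffix positions
    K = len(idx)

    new_lcp = np.zeros(K + 1, dtype=np.int64)
    if K > 1:
        # stored lcp entry t is the LCP of suffixes t-1, t (0-based), so the
        # LCP of kept pair (idx[t], idx[t+1]) is min stored[idx[t]+1 .. idx[t+1]]
        mins = np.minimum.reduceat(index.lcp, idx + 1)
        new_lcp[1:K] = mins[:-1]

    return EbwtIndex(
        ebwt=index.ebwt[idx],
        lcp=new_lcp,
        cda=index.cda[idx],
        taxa=list(index.taxa),
        da=index.da[idx] if index.da is not None else None,
    )


def _part(prefix: Path, ext: str) -> Path:
    return prefix.parent / f"{prefix.name}.{ext}"


def write_index(index: EbwtIndex, prefix: str | Path) -> None:
    """Write the declared binary dialect: .ebwt / .lcp / .cda / .json.

    One byte per eBWT symbol ('A','C','G','T', '#' for every end-marker);
    little-endian uint32 for lcp (N+1 entries) and cda (N entries); a JSON
    sidecar header carries version, N, l and the taxon names.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(_part(prefix, "ebwt"), "wb") as fh:
        fh.write(index.ebwt.tobytes())
    with open(_part(prefix, "lcp"), "wb") as fh:
        fh.write(index.lcp.astype("<u4").tobytes())
    with open(_part(prefix, "cda"), "wb") as fh:
        fh.write(index.cda.astype("<u4").tobytes())
    header = {
        "version": _DIALECT_VERSION,
        "N": index.n,
        "ell": index.n_taxa,
        "taxa": list(index.taxa),
    }
    with open(_part(prefix, "json"), "w") as fh:
        json.dump(header, fh, indent=1)
        fh.write("\n")


def read_index(prefix: str | Path) -> EbwtIndex:
    """Read the dialect written by :func:`write_index`, validating lengths."""
    prefix = Path(prefix)
    try:
        with open(_part(prefix, "json")) as fh:
            header = json.load(fh)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"missing index header {prefix}.json") from exc
    if header.get("version") != _DIALECT_VERSION:
        raise ValueError(f"unsupported index dialect version {header.get('version')}")
    N = int(header["N"])
    taxa = list(header["taxa"])
    if len(taxa) != int(header["ell"]):
        raise ValueError("header taxon list disagrees with ell")

    ebwt = np.fromfile(_part(prefix, "ebwt"), dtype=np.uint8)
    lcp = np.fromfile(_part(prefix, "lcp"), dtype="<u4").astype(np.int64)
    cda = np.fromfile(_part(prefix, "cda"), dtype="<u4").astype(np.int32)
    if len(ebwt) != N:
        raise ValueError(f"{prefix}.ebwt holds {len(ebwt)} symbols, header says {N}")
    if len(lcp) != N + 1:
        raise ValueError(f"{prefix}.lcp holds {len(lcp)} entries, expected N+1={N + 1}")
    if len(cda) != N:
        raise ValueError(f"{prefix}.cda holds {len(cda)} entries, expected N={N}")
    return EbwtIndex(ebwt=ebwt, lcp=lcp, cda=cda, taxa=taxa)
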