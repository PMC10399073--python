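"""Reading per-taxon FASTA inputs and assembling the colored string collection.

The method operates on an ordered collection of DNA strings in which every
string carries a *color*: the index (1..l) of the taxon it belongs to.  A taxon
may own many strings (reads, contigs, a genome, optionally augmented by reverse
complements); downstream the collection is only ever seen through its eBWT,
LCP array and color document array.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Collection",
    "read_fasta",
    "reverse_complement",
    "build_collection",
    "read_manifest",
]

_ACGT_RUN = re.compile(r"[ACGT]+")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class Collection:
    """Ordered, colored string collection over {A,C,G,T}.

    ``strings[i]`` belongs to the taxon ``taxa[colors[i] - 1]``; colors are
    1-based taxon indices assigned in manifest order.  ``N`` counts every
    symbol plus one end-marker per string, the length of the eBWT.
    """

    taxa: list[str]
    colors: list[int]
    strings: list[str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_strings(self) -> int:
        return len(self.strings)

    @property
    def N(self) -> int:
        return sum(len(s) + 1 for s in self.strings)

    def validate(self) -> None:
        ell = len(self.taxa)
        if ell < 1:
            raise ValueError("collection needs at least one taxon")
        if len(self.colors) != len(self.strings):
            raise ValueError("colors and strings must have equal length")
        if not self.strings:
            raise ValueError("collection holds no strings")
        seen: set[int] = set()
        for c in self.colors:
            if not 1 <= c <= ell:
                raise ValueError(f"color {c} outside 1..{ell}")
            seen.add(c)
        if seen != set(range(1, ell + 1)):
            missing = sorted(set(range(1, ell + 1)) - seen)
            raise ValueError(f"taxa with no strings: {missing}")
        for s in self.strings:
            if not s or _ACGT_RUN.fullmatch(s) is None:
                raise ValueError("strings must be non-empty and over {A,C,G,T}")


def _sanitize(seq: str, min_run_length: int) -> list[str]:
    # Non-ACGT characters (N, IUPAC ambiguity codes, ...) split a record into
    # its maximal ACGT runs; runs shorter than min_run_length are dropped.
    runs = _ACGT_RUN.findall(seq.upper())
    return [r for r in runs if len(r) >= min_run_length]


def read_fasta(path: str | Path, min_run_length: int = 1) -> list[str]:
    """Read a FASTA file into a list of sanitized uppercase ACGT strings.

    Records are returned in file order.  A record containing characters
    outside {A,C,G,T} contributes one string per maximal ACGT run (runs
    shorter than ``min_run_length`` are discarded); for noisy read sets a
    sensible floor is twice the minimum context length k_m.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[str] = []
    saw_record = False
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            saw_record = True
            out.extend(_sanitize(str(rec.seq), min_run_length))
    except ValueError as exc:  # biopython reports the offending content
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    if not saw_record:
        raise ValueError(f"empty or non-FASTA file: {path}")
    return out


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    if _ACGT_RUN.fullmatch(seq) is None:
        raise ValueError("reverse_complement requires a non-empty ACGT string")
    return seq.translate(_COMPLEMENT)[::-1]


def read_manifest(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a two-column TSV ``taxon<TAB>path`` into an ordered manifest.

    Repeated taxon names accumulate files under the first occurrence, so a
    taxon's sequencing runs may be listed on consecutive rows.
    """
    path = Path(path)
    order: list[str] = []
    files: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>path'")
            taxon, fp = parts
            if taxon not in files:
                order.append(taxon)
                files[taxon] = []
            files[taxon].append(fp)
    if not order:
        raise ValueError(f"manifest {path} lists no taxa")
    return [(t, files[t]) for t in order]


def build_collection(
    manifest: Sequence[tuple[str, Iterable[str | Path]]],
    add_rc: bool = False,
    min_run_length: int = 1,
) -> Collection:
    """Assemble the ordered collection from a taxon -> files manifest.

    Strings are ordered taxon-by-taxon (manifest order), then file order,
    then record order.  With ``add_rc`` every string is immediately followed
    by its reverse complement under the same color, which makes shared
    contexts visible regardless of the strand a read was sampled from.
    """
    if len(manifest) < 2:
        raise ValueError("need at least two taxa")
    names = [t for t, _ in manifest]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate taxon name(s): {dup}")
    taxa: list[str] = []
    colors: list[int] = []
    strings: list[str] = []
    for color, (taxon, paths) in enumerate(manifest, start=1):
        taxa.append(taxon)
        count = 0
        for fp in paths:
            for s in read_fasta(fp, min_run_length=min_run_length):
                strings.append(s)
                colors.append(color)
                count += 1
                if add_rc:
                    strings.append(reverse_complement(s))
                    colors.append(color)
                    count += 1
        if count == 0:
            raise ValueError(f"taxon {taxon!r} contributed no sequences")
    return Collection(taxa=taxa, colors=colors, strings=strings)


def collection_from_strings(
    taxa: Sequence[str],
    colored_strings: Sequence[tuple[int, str]],
    add_rc: bool = False,
) -> Collection:
    """Build a Collection directly from in-memory (color, string) pairs."""
    colors: list[int] = []
    strings: list[str] = []
    for color, s in colored_strings:
        colors.append(color)
        strings.append(s)
        if add_rc:
            colors.append(color)
            strings.append(reverse_complement(s))
    return Collection(taxa=list(taxa), colors=colors, strings=strings)
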