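"""Genome sequence and interval-mask I/O.

Sequences are normalized to the five-letter alphabet {A, C, G, T, N} on
load: case is folded to upper and every IUPAC ambiguity code other than N
becomes N, because the downstream model is defined only on the four
unambiguous bases.  All coordinates are 0-based half-open internally; BED
files keep their native convention on disk (which is the same one).

Only the forward strand is ever read.  The model's complementarity
argument accounts for the reverse strand analytically, so reverse
complement counts must never be added on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = "ACGTN"

# every byte that is not an unambiguous base (either case) maps to N
_NORMALIZE = bytes(
    ord(chr(b).upper()) if chr(b).upper() in "ACGT" else ord("N")
    for b in range(256)
)


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class BedParseError(ValueError):
    """Raised when a BED file has an invalid record."""


@dataclass(frozen=True)
class Contig:
    """A named sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class IntervalSet:
    """Per-contig sorted, non-overlapping half-open intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_raw(cls, raw: Mapping[str, Iterable[tuple[int, int]]]) -> "IntervalSet":
        """Build a normalized set: sorts and merges overlapping/adjacent spans."""
        out: dict[str, list[tuple[int, int]]] = {}
        for contig_id, spans in raw.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(spans):
                if start < 0 or start >= end:
                    raise ValueError(f"invalid interval ({start}, {end}) on {contig_id!r}")
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            out[contig_id] = merged
        return cls(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        for src in (self.intervals, other.intervals):
            for cid, spans in src.items():
                raw.setdefault(cid, []).extend(spans)
        return IntervalSet.from_raw(raw)

    def total_bases(self) -> int:
        return sum(e - s for spans in self.intervals.values() for s, e in spans)

    def __bool__(self) -> bool:
        return any(self.intervals.values())


@dataclass(frozen=True)
class GenomeStats:
    """Ungapped genome size summaries.

    L counts A/C/G/T positions after gap (N) removal; n_dinucleotides is
    the number of valid dinucleotide windows, i.e. adjacent same-contig
    position pairs with both letters unambiguous.  On a gap-free single
    sequence of length n this is exactly n - 1.
    """

    L: int
    n_dinucleotides: int

    def __post_init__(self) -> None:
        if self.L < 0 or self.n_dinucleotides < 0:
            raise ValueError("genome stats must be nonnegative")


def _normalize(seq: str) -> str:
    return seq.encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (multi-)FASTA file into normalized contigs, in file order.

    Soft-masked (lowercase) letters are kept as their uppercase base;
    ambiguity codes other than N become N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            seq = _normalize(str(record.seq))
            if not seq:
                raise FastaParseError(f"{path}: record {record.id!r} has no sequence")
            contigs.append(Contig(id=record.id, seq=seq))
    if not contigs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return contigs


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED file into a normalized IntervalSet.

    Overlapping records on the same contig are merged; an empty file
    yields an empty set.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            raw.setdefault(fields[0], []).append((start, end))
    return IntervalSet.from_raw(raw)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for cid in intervals.intervals:
            for start, end in intervals.intervals[cid]:
                handle.write(f"{cid}\t{start}\t{end}\n")


def apply_mask(contigs: Sequence[Contig], intervals: IntervalSet) -> list[Contig]:
    """Replace masked positions with N so no k-mer window spans them.

    Intervals referencing unknown contig ids are ignored with a warning.
    Idempotent: masking twice equals masking once.
    """
    known = {c.id for c in contigs}
    for cid in intervals.intervals:
        if cid not in known:
            logger.warning("mask interval references unknown contig %r; ignored", cid)
    out: list[Contig] = []
    for contig in contigs:
        spans = intervals.intervals.get(contig.id, [])
        if not spans:
            out.append(contig)
            continue
        arr = bytearray(contig.seq, "ascii")
        n = len(arr)
        for start, end in spans:
            if start >= n:
                continue
            arr[start:min(end, n)] = b"N" * (min(end, n) - start)
        out.append(Contig(id=contig.id, seq=arr.decode("ascii")))
    return out


def genome_stats(contigs: Sequence[Contig]) -> GenomeStats:
    """Ungapped length L and valid dinucleotide-window count.

    Dinucleotides never span contig boundaries or N runs; for a gap-free
    single contig of length n this returns L = n, n_dinucleotides = n - 1.
    """
    L = 0
    pairs = 0
    for contig in contigs:
        arr = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
        valid = arr != ord("N")
        L += int(valid.sum())
        if len(arr) > 1:
            pairs += int((valid[:-1] & valid[1:]).sum())
    return GenomeStats(L=L, n_dinucleotides=pairs)
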