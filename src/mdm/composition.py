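"""k-mer counting and dinucleotide composition statistics.

Counting is over overlapping forward-strand windows at step 1; windows
containing N are excluded and windows never span contig boundaries.  GC
content uses the ungapped length L as denominator (N excluded).

Proportions are kept at full precision here; rounding to the 2 decimals
conventional in composition tables happens only in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import Contig

NUCLEOTIDES = "ACGT"

DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

#: The ten complementary dinucleotide classes in conventional table order.
#: Four dinucleotides (ApT, CpG, GpC, TpA) are their own reverse
#: complements and form singleton classes.
POOLED_CLASSES: dict[str, tuple[str, ...]] = {
    "ApA/TpT": ("AA", "TT"),
    "ApC/GpT": ("AC", "GT"),
    "ApG/CpT": ("AG", "CT"),
    "ApT": ("AT",),
    "CpA/TpG": ("CA", "TG"),
    "CpC/GpG": ("CC", "GG"),
    "CpG": ("CG",),
    "GpA/TpC": ("GA", "TC"),
    "GpC": ("GC",),
    "TpA": ("TA",),
}

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(NUCLEOTIDES):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerCounts:
    """Counts of all 4**k k-mers over {A, C, G, T}; N-windows excluded."""

    k: int
    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3):
            raise ValueError("k must be 1, 2, or 3")
        expected_keys = {"".join(p) for p in product(NUCLEOTIDES, repeat=self.k)}
        if set(self.counts) != expected_keys:
            raise ValueError(f"counts must have all {4 ** self.k} k-mer keys")
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not match the sum of counts")

    def __getitem__(self, kmer: str) -> int:
        return self.counts[kmer]


@dataclass(frozen=True)
class DinucleotideProfile:
    """The 16 dinucleotide proportions (%) plus GC content of a genome state.

    ``source`` tags whether the profile was measured ("observed"), assumed
    ("initial"), or predicted by the model ("expected").
    """

    proportions: Mapping[str, float]
    gc_percent: float
    source: str = "observed"

    def __post_init__(self) -> None:
        if set(self.proportions) != set(DINUCLEOTIDES):
            raise ValueError("profile must cover all 16 dinucleotides")
        total = sum(self.proportions.values())
        if abs(total - 100.0) > 1e-9 * 100.0:
            raise ValueError(f"proportions sum to {total}, expected 100")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent out of [0, 100]")
        if self.source not in ("observed", "initial", "expected"):
            raise ValueError(f"unknown source tag {self.source!r}")

    def __getitem__(self, dinuc: str) -> float:
        return self.proportions[dinuc]


@dataclass(frozen=True)
class PooledProfile:
    """Proportions (%) of the ten complementary dinucleotide classes."""

    values: Mapping[str, float]
    gc_percent: float | None = None
    source: str = "observed"

    def __post_init__(self) -> None:
        if set(self.values) != set(POOLED_CLASSES):
            raise ValueError("pooled profile must cover the 10 classes")

    def __getitem__(self, cls: str) -> float:
        return self.values[cls]


def _codes(contig: Contig) -> np.ndarray:
    return _CODE[np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)]


def count_kmers(contigs: Sequence[Contig] | Contig, k: int) -> KmerCounts:
    """Count overlapping k-mers (k = 1, 2, 3) on the forward strand.

    Windows containing N are skipped; windows never span contigs.
    """
    if isinstance(contigs, Contig):
        contigs = [contigs]
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2, or 3")
    acc = np.zeros(4 ** k, dtype=np.int64)
    for contig in contigs:
        codes = _codes(contig)
        if len(codes) < k:
            continue
        idx = codes[: len(codes) - k + 1].astype(np.int64)
        valid = codes[: len(codes) - k + 1] < 4
        for j in range(1, k):
            nxt = codes[j : len(codes) - k + 1 + j]
            valid &= nxt < 4
            idx = idx * 4 + nxt
        idx = idx[valid]
        if len(idx):
            acc += np.bincount(idx, minlength=4 ** k)
    kmers = ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]
    counts = {kmer: int(acc[i]) for i, kmer in enumerate(kmers)}
    return KmerCounts(k=k, counts=counts, total=int(acc.sum()))


def observed_profile(contigs: Sequence[Contig] | Contig) -> DinucleotideProfile:
    """Measure the 16 dinucleotide proportions and GC content of a genome.

    proportion(x) = 100 * count(x) / total dinucleotide windows;
    GC% = 100 * (#C + #G) / L with L the ungapped length.
    """
    if isinstance(contigs, Contig):
        contigs = [contigs]
    mono = count_kmers(contigs, 1)
    di = count_kmers(contigs, 2)
    if di.total == 0:
        raise ValueError("no valid dinucleotide window in input")
    proportions = {x: 100.0 * di[x] / di.total for x in DINUCLEOTIDES}
    L = mono.total
    gc = 100.0 * (mono["C"] + mono["G"]) / L
    return DinucleotideProfile(proportions=proportions, gc_percent=gc, source="observed")


def pool_profile(profile: DinucleotideProfile) -> PooledProfile:
    """Collapse 16 dinucleotides into the 10 complementary classes."""
    values = {
        cls: sum(profile[d] for d in members)
        for cls, members in POOLED_CLASSES.items()
    }
    return PooledProfile(values=values, gc_percent=profile.gc_percent, source=profile.source)


def expected_cpg_current(profile: DinucleotideProfile) -> float:
    """Expected CpG% of the current genome state from its GC content alone.

    Under independent positions the expected CpG frequency is the product
    of the C and G frequencies, each one-half of the GC content:
    100 * (gc/2) * (gc/2) with gc the GC fraction.  At GC 50% this is
    6.25%.
    """
    gc = profile.gc_percent / 100.0
    return 100.0 * (gc / 2.0) * (gc / 2.0)
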