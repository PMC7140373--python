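"""Estimation of the eight CpG flanking-base probabilities.

Two estimators are provided.  The trinucleotide method takes the
empirical distribution of the base 5' of CpG (share of ApCpG, CpCpG,
GpCpG, TpCpG among all NpCpG) and, independently, of the base 3' of CpG
(share of CpGpA..CpGpT among all CpGpM).  The GC method uses the
strand-complementarity approximation P_A ~ P'_T, P_C ~ P'_G etc. to set
all eight parameters from the GC content alone: the two G/C-flank
probabilities are gc/2 and the two A/T-flank ones (1 - gc)/2.

The trinucleotide method is preferred in practice: cumulative CpG decay
changes the GC content over time, so GC-derived parameters are biased
when the current GC content differs from the historical one.

CpG islands are typically unmethylated and must be excluded before
counting; `estimate_from_genome` masks them (plus any user mask) first.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .cgi import CgiParams, find_islands, islands_to_mask
from .composition import KmerCounts, count_kmers
from .core import ContextProbabilities
from .sequence_io import Contig, IntervalSet, apply_mask

logger = logging.getLogger(__name__)

TRINUCLEOTIDE = "trinucleotide"
GC = "gc"


class NoCpGContextError(ValueError):
    """The (masked) genome contains no CpG-context trinucleotides, so the
    flanking-base distributions are undefined and the model inapplicable."""


def estimate_trinucleotide(tri: KmerCounts) -> ContextProbabilities:
    """Flanking-base probabilities from trinucleotide counts (k = 3).

    P_N = S_NCG / (S_ACG + S_CCG + S_GCG + S_TCG) and
    P'_M = S_CGM / (S_CGA + S_CGC + S_CGG + S_CGT); both quadruples are
    exactly normalized by construction.
    """
    if tri.k != 3:
        raise ValueError("trinucleotide estimation requires k = 3 counts")
    ncg = {n: tri[n + "CG"] for n in "ACGT"}
    cgm = {m: tri["CG" + m] for m in "ACGT"}
    denom_p = sum(ncg.values())
    denom_pp = sum(cgm.values())
    if denom_p == 0 or denom_pp == 0:
        raise NoCpGContextError(
            "no NpCpG/CpGpM trinucleotides in input: the genome (after "
            "masking) has no CpG context and the model is inapplicable"
        )
    return ContextProbabilities(
        pA=ncg["A"] / denom_p,
        pC=ncg["C"] / denom_p,
        pG=ncg["G"] / denom_p,
        pT=ncg["T"] / denom_p,
        ppA=cgm["A"] / denom_pp,
        ppC=cgm["C"] / denom_pp,
        ppG=cgm["G"] / denom_pp,
        ppT=cgm["T"] / denom_pp,
    )


def estimate_gc(gc_percent: float) -> ContextProbabilities:
    """Flanking-base probabilities from the GC content alone.

    With p = gc/100: the A and T flanks each get (1 - p)/2, the C and G
    flanks each get p/2, identically for both quadruples.
    """
    if not 0.0 < gc_percent < 100.0:
        raise ValueError(f"gc_percent must be in (0, 100), got {gc_percent}")
    p = gc_percent / 100.0
    at = (1.0 - p) / 2.0
    cg = p / 2.0
    return ContextProbabilities(pA=at, pC=cg, pG=cg, pT=at, ppA=at, ppC=cg, ppG=cg, ppT=at)


def estimate_from_genome(
    contigs: Sequence[Contig] | Contig,
    mask: IntervalSet | None = None,
    method: str = TRINUCLEOTIDE,
    mask_islands: bool = True,
    cgi_params: CgiParams | None = None,
) -> ContextProbabilities:
    """Mask, count, and estimate in one step.

    The CpG-island mask (detected on the unmasked input when
    ``mask_islands`` is true) is united with any user-supplied mask; the
    chosen estimator then runs on the masked forward strand.
    """
    if isinstance(contigs, Contig):
        contigs = [contigs]
    if method not in (TRINUCLEOTIDE, GC):
        raise ValueError(f"unknown estimation method {method!r}")

    full_mask = mask if mask is not None else IntervalSet()
    if mask_islands:
        islands = find_islands(contigs, cgi_params)
        full_mask = full_mask.union(islands_to_mask(islands))
    masked = apply_mask(contigs, full_mask) if full_mask else list(contigs)
    logger.info(
        "estimating context probabilities (%s method), %d bases masked",
        method,
        full_mask.total_bases(),
    )

    if method == TRINUCLEOTIDE:
        return estimate_trinucleotide(count_kmers(masked, 3))
    mono = count_kmers(masked, 1)
    if mono.total == 0:
        raise NoCpGContextError("masked genome has no unambiguous bases")
    gc_percent = 100.0 * (mono["C"] + mono["G"]) / mono.total
    return estimate_gc(gc_percent)
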