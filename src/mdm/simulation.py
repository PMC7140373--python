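"""Synthetic genomes and forward simulation of methylation-driven CpG decay.

The generator draws i.i.d. bases at a configurable GC content, which
realizes the product-form initial state in expectation, optionally with
embedded CpG-rich blocks that mimic CpG islands.  The decay simulator
destroys CpG sites one event at a time: each event picks a CpG uniformly
from the *current* set and converts it to TpG (C->T, methylation on the
forward strand) or CpA (G->A, methylation on the reverse strand read
forward) with a fair coin.  Exactly one letter changes per event, the
sequence length and total dinucleotide count are conserved, and — since
neither substitution can create a new CpG — each event removes exactly
one CpG from the genome.

`oracle_check` is the independent validation of the closed-form change
matrix: it compares the empirical per-dinucleotide count changes of a
simulation against the Q prediction, scaled by a per-event
variance bound.  The closed-form model treats events as independent of
one another, so agreement is expected only in the sparse regime
(events per base <= ~0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import DINUCLEOTIDES, NUCLEOTIDES, count_kmers
from .core import ChangeMatrix, ContextProbabilities, matrix_Q
from .sequence_io import Contig


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-genome parameters.

    cgi_blocks: optional (block_length, spacing) pairs; for each pair,
    tandem-CG blocks of the given length are written over the background
    every ``spacing`` bases.  One seed governs everything downstream.
    """

    length: int
    gc: float = 50.0
    n_events: int = 0
    seed: int = 0
    cgi_blocks: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length <= 1:
            raise ValueError("length must be > 1")
        if not 0.0 < self.gc <= 100.0:
            raise ValueError("gc must be in (0, 100]")
        if self.n_events < 0:
            raise ValueError("n_events must be nonnegative")


@dataclass(frozen=True)
class MutationEvent:
    """One simulated CpG decay event: the CpG start position and which
    strand carried the methylated cytosine ("TpG" = forward C->T at
    `position`, "CpA" = reverse, forward G->A at `position` + 1)."""

    position: int
    outcome: str


def generate_genome(config: SimConfig) -> Contig:
    """Draw an i.i.d. genome at the configured GC content.

    freq(C) = freq(G) = gc/200, freq(A) = freq(T) = (100 - gc)/200;
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc / 100.0
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.length, p=probs)
    arr = np.frombuffer(NUCLEOTIDES.encode("ascii"), dtype=np.uint8)[codes].copy()
    for block_len, spacing in config.cgi_blocks:
        block = np.frombuffer(
            ("CG" * (block_len // 2 + 1))[:block_len].encode("ascii"), dtype=np.uint8
        )
        pos = spacing
        while pos + block_len <= config.length:
            arr[pos : pos + block_len] = block
            pos += spacing + block_len
    return Contig(id=f"sim_gc{config.gc:g}_seed{config.seed}", seq=arr.tobytes().decode("ascii"))


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def simulate_cpg_decay(
    contig: Contig,
    n_events: int,
    seed: int = 0,
    p_tpg: float = 0.5,
) -> tuple[Contig, list[MutationEvent]]:
    """Destroy ``n_events`` CpG sites by C->T / G->A substitution.

    Each event is uniform over the surviving CpG set; ``p_tpg`` is the
    probability of the forward-strand (TpG) branch, a fair coin by
    default.  Because no substitution here can create a CpG, sequential
    uniform choice equals uniform sampling without replacement.  Returns
    the mutated contig and the event log.
    """
    positions = _cpg_positions(contig.seq)
    if n_events > len(positions):
        raise ValueError(
            f"requested {n_events} events but only {len(positions)} CpG sites remain"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(positions, size=n_events, replace=False)
    branches = rng.random(n_events) < p_tpg
    arr = bytearray(contig.seq, "ascii")
    events: list[MutationEvent] = []
    for pos, is_tpg in zip(chosen.tolist(), branches.tolist()):
        if is_tpg:
            arr[pos] = ord("T")
            events.append(MutationEvent(position=pos, outcome="TpG"))
        else:
            arr[pos + 1] = ord("A")
            events.append(MutationEvent(position=pos, outcome="CpA"))
    return Contig(id=contig.id, seq=arr.decode("ascii")), events


def _per_event_moments(params: ContextProbabilities) -> tuple[dict[str, float], dict[str, float]]:
    """Mean and variance of the per-event count change of each dinucleotide.

    Enumerates the four possible flanks of each branch: a TpG-branch
    event with flank N changes CpG -1, TpG +1, NpC -1, NpT +1; a
    CpA-branch event with flank M changes CpG -1, CpA +1, GpM -1,
    ApM +1.  Flank probabilities come from ``params``; branches are
    equiprobable.
    """
    mean = {d: 0.0 for d in DINUCLEOTIDES}
    second = {d: 0.0 for d in DINUCLEOTIDES}
    for branch_prob, flanks, deltas in (
        (0.5, params.p, lambda n: {"CG": -1, "TG": +1, n + "C": -1, n + "T": +1}),
        (0.5, params.pp, lambda m: {"CG": -1, "CA": +1, "G" + m: -1, "A" + m: +1}),
    ):
        for flank, fp in zip(NUCLEOTIDES, flanks):
            change: dict[str, int] = {}
            for d, c in deltas(flank).items():
                change[d] = change.get(d, 0) + c
            for d, c in change.items():
                mean[d] += branch_prob * fp * c
                second[d] += branch_prob * fp * c * c
    var = {d: second[d] - mean[d] ** 2 for d in DINUCLEOTIDES}
    return mean, var


def oracle_check(
    before: Contig,
    after: Contig,
    params: ContextProbabilities,
    n_events: int,
) -> dict[str, float]:
    """z-score of (empirical - predicted) count change per dinucleotide.

    The prediction is Q with H = n_events; the scale is a binomial-style
    standard deviation from the per-event change distribution under
    ``params``.  Dinucleotides the model leaves untouched (zero
    per-event variance, e.g. TpA) get z = 0 only if the empirical change
    is also zero, else infinity.
    """
    counts_before = count_kmers(before, 2)
    counts_after = count_kmers(after, 2)
    q: ChangeMatrix = matrix_Q(params, float(n_events))
    _, var = _per_event_moments(params)
    z: dict[str, float] = {}
    for d in DINUCLEOTIDES:
        emp = counts_after[d] - counts_before[d]
        pred = q[d]
        sd = float(np.sqrt(n_events * var[d])) if n_events else 0.0
        resid = emp - pred
        if sd == 0.0:
            z[d] = 0.0 if resid == 0.0 else float(np.inf)
        else:
            z[d] = resid / sd
    return z
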