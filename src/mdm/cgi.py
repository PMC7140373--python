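"""CpG island detection and masking.

A CpG island (CGI) is a stretch of DNA longer than 200 bp with GC
content above 50% and observed-to-expected CpG ratio above 0.6.  CGIs
are typically unmethylated in normal cells, so they must be masked out
before estimating the flanking-base probabilities of methylation-driven
CpG decay.

The detector is a deterministic sliding-window scanner over the
published criteria: a window (default 200 bp) slides at step 1, window
start positions where all criteria hold are flagged, sustained runs of
flagged starts (at least one window long — single qualifying windows
are indistinguishable from background fluctuation at these thresholds)
are extended to window ends and merged when separated by less than a
window, then each candidate is trimmed until the region as a whole
satisfies every criterion.  All three thresholds are strict
inequalities and are exposed as configuration.  The run requirement
puts the detection floor at about twice the window size; at the default
geometry, islands shorter than ~400 bp are not called.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import Contig, IntervalSet


@dataclass(frozen=True)
class CgiParams:
    """Detection thresholds and scan geometry (defaults: the standard
    >200 bp / >50% GC / >0.6 O/E definition, 200 bp window, step 1)."""

    min_length: int = 200
    min_gc: float = 50.0
    min_oe: float = 0.6
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")
        if not 0.0 < self.min_gc < 100.0:
            raise ValueError("min_gc must be in (0, 100)")
        if self.min_oe <= 0.0:
            raise ValueError("min_oe must be positive")
        if self.window < 2 or self.step < 1:
            raise ValueError("window must be >= 2 and step >= 1")


@dataclass(frozen=True)
class Island:
    """A detected CpG island with its whole-region statistics."""

    contig_id: str
    start: int
    end: int
    gc: float
    oe: float

    def __len__(self) -> int:
        return self.end - self.start


def cpg_oe_ratio(window_seq: str) -> float:
    """Observed-to-expected CpG ratio of a sequence window.

    Expected CpG count under base independence is #C * #G / length; a
    window without both C and G has expected 0 and the ratio is reported
    as 0 by convention.
    """
    n = len(window_seq)
    if n == 0:
        return 0.0
    c = window_seq.count("C")
    g = window_seq.count("G")
    if c == 0 or g == 0:
        return 0.0
    obs = window_seq.count("CG")
    return obs / (c * g / n)


def _region_stats(seq: str, start: int, end: int) -> tuple[float, float]:
    """(GC%, O/E) of a whole region, N excluded from the GC denominator."""
    sub = seq[start:end]
    acgt = sum(sub.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0, 0.0
    c = sub.count("C")
    g = sub.count("G")
    gc = 100.0 * (c + g) / acgt
    return gc, cpg_oe_ratio(sub)


def _flagged_starts(seq: str, params: CgiParams) -> np.ndarray:
    """Boolean array over window-start positions where the window
    contains no N and passes both the GC and O/E thresholds."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    w = params.window
    if n < w:
        return np.zeros(0, dtype=bool)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def wsum(x: np.ndarray, width: int) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(x)))
        return cs[width:] - cs[: n - width + 1]

    c_w = wsum(is_c, w)
    g_w = wsum(is_g, w)
    n_w = wsum(is_n, w)
    # CpG starts fully inside the window: positions i .. i+w-2
    cg_prefix = np.concatenate(([0], np.cumsum(is_cg)))
    cg_w = cg_prefix[np.arange(w - 1, n)] - cg_prefix[np.arange(0, n - w + 1)]

    gc_pct = 100.0 * (c_w + g_w) / w
    expected = c_w * g_w / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, cg_w / np.where(expected > 0, expected, 1.0), 0.0)
    flagged = (n_w == 0) & (gc_pct > params.min_gc) & (oe > params.min_oe)
    if params.step > 1:
        keep = np.zeros_like(flagged)
        keep[:: params.step] = True
        flagged &= keep
    return flagged


class _Prefixes:
    """O(1) whole-region GC% and O/E via prefix sums."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        is_cg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        self.c = np.concatenate(([0], np.cumsum(arr == ord("C"))))
        self.g = np.concatenate(([0], np.cumsum(arr == ord("G"))))
        self.acgt = np.concatenate(([0], np.cumsum(arr != ord("N"))))
        self.cg = np.concatenate(([0], np.cumsum(is_cg)))

    def stats(self, start: int, end: int) -> tuple[float, float]:
        c = int(self.c[end] - self.c[start])
        g = int(self.g[end] - self.g[start])
        acgt = int(self.acgt[end] - self.acgt[start])
        if acgt == 0 or c == 0 or g == 0:
            return 0.0, 0.0
        cpg = int(self.cg[max(end - 1, start)] - self.cg[start])
        n = end - start
        return 100.0 * (c + g) / acgt, cpg / (c * g / n)


def _trim(pfx: _Prefixes, start: int, end: int, params: CgiParams) -> tuple[int, int] | None:
    """Shrink a candidate until the whole region passes all criteria.

    Greedy: each step removes the terminal base whose removal best
    restores the currently failing criterion, which strips low-GC flank
    while keeping the CpG-dense core.  Gives up below min_length.
    Deterministic for fixed input.
    """
    while end - start >= params.min_length:
        gc, oe = pfx.stats(start, end)
        if gc > params.min_gc and oe > params.min_oe:
            return start, end
        gc_l, oe_l = pfx.stats(start + 1, end)
        gc_r, oe_r = pfx.stats(start, end - 1)
        if gc <= params.min_gc:
            take_left = gc_l > gc_r
        else:
            take_left = oe_l > oe_r
        if take_left:
            start += 1
        else:
            end -= 1
    return None


def find_islands(
    contigs: Sequence[Contig] | Contig,
    params: CgiParams | None = None,
) -> list[Island]:
    """Scan contigs for CpG islands under the configured criteria.

    Every reported island, re-evaluated as a whole region, satisfies all
    three thresholds; output is deterministic and sorted by position.
    """
    if isinstance(contigs, Contig):
        contigs = [contigs]
    params = params or CgiParams()
    out: list[Island] = []
    for contig in contigs:
        flagged = _flagged_starts(contig.seq, params)
        if not flagged.any():
            continue
        pfx = _Prefixes(contig.seq)
        # runs of flagged starts -> candidate [run_start, run_end + window);
        # only sustained runs (>= one window of consecutive flagged starts)
        # become candidates: a single window passing the thresholds is
        # indistinguishable from background fluctuation at these cutoffs,
        # so the detection floor is ~2*window - 1 bases
        idx = np.flatnonzero(flagged)
        breaks = np.flatnonzero(np.diff(idx) > params.step)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)),
            np.concatenate((breaks, [len(idx) - 1])),
        )
        candidates = [
            (int(idx[a]), int(idx[b]) + params.window)
            for a, b in run_bounds
            if idx[b] - idx[a] + 1 >= params.window / params.step
        ]
        # merge candidates separated by less than one window
        merged: list[list[int]] = []
        for s, e in candidates:
            if merged and s - merged[-1][1] < params.window:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            trimmed = _trim(pfx, s, min(e, len(contig.seq)), params)
            if trimmed is None:
                continue
            ts, te = trimmed
            gc, oe = pfx.stats(ts, te)
            out.append(Island(contig_id=contig.id, start=ts, end=te, gc=gc, oe=oe))
    return out


def islands_to_mask(islands: Sequence[Island]) -> IntervalSet:
    """Collapse island spans into a normalized mask."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for isl in islands:
        raw.setdefault(isl.contig_id, []).append((isl.start, isl.end))
    return IntervalSet.from_raw(raw)


def write_islands_bed(islands: Sequence[Island], path: str | Path) -> None:
    """BED export: name "CGI", score = round(100 * O/E)."""
    with open(path, "w") as handle:
        for isl in islands:
            handle.write(
                f"{isl.contig_id}\t{isl.start}\t{isl.end}\tCGI\t{round(100 * isl.oe)}\n"
            )
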