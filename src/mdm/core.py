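"""The methylation-driven model (MDM) of dinucleotide evolution.

A methylated CpG deaminates to TpG on the strand carrying the 5mC; by
complementarity the same event read on the other strand is CpG -> CpA.
Each event therefore destroys one CpG and perturbs the counts of the
neighbouring dinucleotides in a way that depends only on the flanking
base: for a forward-strand event in context NpCpG the dinucleotide NpC
is lost and NpT gained, and for a reverse-strand event (CpGpM on the
forward strand) GpM is lost and ApM gained.

With P_N the distribution of the 5' flank N and P'_M of the 3' flank M,
the per-event count changes are the 4x4 matrices D (NpCpG -> NpTpG) and
D' (CpGpM -> CpApM); a budget of H destroyed CpGs, split evenly between
the two strands, shifts the dinucleotide counts by Q = (H/2) (D + D').
Expected proportions are the assumed initial proportions plus the Q
shift over the total dinucleotide count, and the expected GC content
drops by one C (or G) per event: GC%_exp = GC_ini% - 100 * H / L.

The model is neutral everywhere else: all non-CpG-context mutations are
assumed to leave the composition unchanged, and the total number of
dinucleotides is conserved (every matrix here has entries summing to 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .composition import (
    DINUCLEOTIDES,
    NUCLEOTIDES,
    POOLED_CLASSES,
    DinucleotideProfile,
)
from .sequence_io import GenomeStats

logger = logging.getLogger(__name__)

_IDX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: Sum tolerance for the two probability quadruples.  Loose enough to
#: accept parameter tables rounded to 4 decimals (worst case 2e-4 off);
#: estimators always produce exactly normalized quadruples.
_SUM_ATOL = 1e-3

TREND_UP = "up"
TREND_DOWN = "down"
TREND_UNCHANGED = "unchanged"
TREND_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ContextProbabilities:
    """CpG flanking-base distributions.

    (pA, pC, pG, pT) is the distribution of the base N immediately 5' of
    a CpG (NpCpG context); (ppA, ppC, ppG, ppT) that of the base M
    immediately 3' (CpGpM context).  Each quadruple sums to 1.
    """

    pA: float
    pC: float
    pG: float
    pT: float
    ppA: float
    ppC: float
    ppG: float
    ppT: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} out of [0, 1]")
        s1 = self.pA + self.pC + self.pG + self.pT
        s2 = self.ppA + self.ppC + self.ppG + self.ppT
        if abs(s1 - 1.0) > _SUM_ATOL or abs(s2 - 1.0) > _SUM_ATOL:
            raise ValueError(f"probability quadruples sum to {s1}, {s2}; expected 1")

    @property
    def p(self) -> tuple[float, float, float, float]:
        return (self.pA, self.pC, self.pG, self.pT)

    @property
    def pp(self) -> tuple[float, float, float, float]:
        return (self.ppA, self.ppC, self.ppG, self.ppT)

    @classmethod
    def uniform(cls) -> "ContextProbabilities":
        return cls(*(0.25,) * 8)


class ChangeMatrix:
    """A 4x4 table of per-mutation dinucleotide count changes.

    Rows index the first base of a dinucleotide, columns the second;
    entries of D, D' and any of their linear combinations sum to 0
    (dinucleotide count conservation).
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (4, 4):
            raise ValueError("change matrix must be 4x4")
        self.values = values

    def __getitem__(self, key: tuple[str, str] | str) -> float:
        if isinstance(key, str):
            key = (key[0], key[1])
        return float(self.values[_IDX[key[0]], _IDX[key[1]]])

    def __add__(self, other: "ChangeMatrix") -> "ChangeMatrix":
        return ChangeMatrix(self.values + other.values)

    def __mul__(self, scalar: float) -> "ChangeMatrix":
        return ChangeMatrix(self.values * scalar)

    __rmul__ = __mul__

    def total(self) -> float:
        return float(self.values.sum())

    def as_dict(self) -> dict[str, float]:
        return {d: self[d] for d in DINUCLEOTIDES}


@dataclass(frozen=True)
class InitialState:
    """Assumed ancestral composition: independent bases at a given GC%.

    Under independence every dinucleotide proportion is the product of
    its base frequencies, with freq(A) = freq(T) = (1 - gc)/2 and
    freq(C) = freq(G) = gc/2.
    """

    gc_ini: float
    profile: DinucleotideProfile

    @property
    def cpg_percent(self) -> float:
        return self.profile["CG"]


@dataclass(frozen=True)
class PredictionResult:
    """Model output: mutation budget, expected composition, and trends."""

    H: float
    expected: DinucleotideProfile
    trends: Mapping[str, str]
    gc_exp: float


def matrix_D(params: ContextProbabilities) -> ChangeMatrix:
    """Count changes per forward-strand event NpCpG -> NpTpG.

    Column C loses the flank-weighted NpC, column T gains NpT; the CpG
    itself becomes a TpG.
    """
    m = np.zeros((4, 4))
    for i, p in enumerate(params.p):
        m[i, _IDX["C"]] = -p
        m[i, _IDX["T"]] = p
    m[_IDX["C"], _IDX["G"]] += -1.0
    m[_IDX["T"], _IDX["G"]] += 1.0
    return ChangeMatrix(m)


def matrix_Dprime(params: ContextProbabilities) -> ChangeMatrix:
    """Count changes per reverse-strand event, seen forward as CpGpM -> CpApM.

    Row A gains the flank-weighted ApM, row G loses GpM; the CpG becomes
    a CpA.  All four entries of row G are negative, including (G, T):
    a CpGpT -> CpApT event destroys one GpT.
    """
    m = np.zeros((4, 4))
    for j, pp in enumerate(params.pp):
        m[_IDX["A"], j] = pp
        m[_IDX["G"], j] = -pp
    m[_IDX["C"], _IDX["A"]] += 1.0
    m[_IDX["C"], _IDX["G"]] += -1.0
    return ChangeMatrix(m)


def matrix_Q(params: ContextProbabilities, H: float) -> ChangeMatrix:
    """Total count change for H events split evenly across strands:
    Q = (H/2) (D + D').  The (C, G) entry scales to -H: every event
    destroys exactly one CpG."""
    return (H / 2.0) * (matrix_D(params) + matrix_Dprime(params))


def initial_state(gc_ini: float) -> InitialState:
    """Product-form initial composition at an assumed GC content (%)."""
    if not 0.0 < gc_ini < 100.0:
        raise ValueError(f"gc_ini must be in (0, 100), got {gc_ini}")
    gc = gc_ini / 100.0
    freq = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    proportions = {n + m: 100.0 * freq[n] * freq[m] for n in NUCLEOTIDES for m in NUCLEOTIDES}
    profile = DinucleotideProfile(proportions=proportions, gc_percent=gc_ini, source="initial")
    return InitialState(gc_ini=gc_ini, profile=profile)


def mutation_budget(
    initial: InitialState,
    observed: DinucleotideProfile,
    stats: GenomeStats,
) -> float:
    """Number of CpG->TpG/CpA events implied by the CpG deficit.

    H = (CpG_ini - CpG_obs) * N with the CpG values as fractions and N
    the total dinucleotide count.  Negative when the observed CpG level
    exceeds the assumed initial one — the model's premise is then
    violated, so a warning is issued rather than an error.
    """
    h = (initial.cpg_percent - observed["CG"]) / 100.0 * stats.n_dinucleotides
    if h < 0:
        warnings.warn(
            "observed CpG exceeds the assumed initial CpG; mutation budget "
            f"H = {h:.4g} is negative and the model premise is violated",
            stacklevel=2,
        )
    return h


def _pooled_shift_sign(params: ContextProbabilities | None, cls: str) -> float:
    """Per-event count shift of a pooled class, from D + D' (H-independent)."""
    assert params is not None
    s = matrix_D(params) + matrix_Dprime(params)
    return sum(s[d] for d in POOLED_CLASSES[cls])


def trend_table(params: ContextProbabilities | None = None) -> dict[str, str]:
    """Changing trend of each pooled class under CpG decay.

    Fourteen of the 16 dinucleotides have trends readable directly from
    the structure of Q; only ApC and GpT depend on the sign of
    (P'_C - P_A) and (P_G - P'_T), so without parameters that class is
    "undetermined".
    """
    trends = {
        "ApA/TpT": TREND_UP,
        "ApG/CpT": TREND_UP,
        "ApT": TREND_UP,
        "CpA/TpG": TREND_UP,
        "CpC/GpG": TREND_DOWN,
        "CpG": TREND_DOWN,
        "GpA/TpC": TREND_DOWN,
        "GpC": TREND_DOWN,
        "TpA": TREND_UNCHANGED,
    }
    if params is None:
        trends["ApC/GpT"] = TREND_UNDETERMINED
    else:
        shift = (params.ppC - params.pA) + (params.pG - params.ppT)
        if shift > 0:
            trends["ApC/GpT"] = TREND_UP
        elif shift < 0:
            trends["ApC/GpT"] = TREND_DOWN
        else:
            trends["ApC/GpT"] = TREND_UNCHANGED
    return {cls: trends[cls] for cls in POOLED_CLASSES}


def predict(
    initial: InitialState,
    observed: DinucleotideProfile,
    params: ContextProbabilities,
    stats: GenomeStats | None = None,
) -> PredictionResult:
    """Predict the current composition from the initial state and CpG deficit.

    Expected proportion of dinucleotide x is its initial proportion plus
    100 * Q_x / N; the expected GC content is GC_ini% - 100 * H / L.  By
    construction the expected CpG equals the observed CpG.

    When ``stats`` is None the infinite-genome limit is used (N/L -> 1),
    which is the right mode when only composition tables are available:
    per-dinucleotide shifts become (CpG%_ini - CpG%_obs)/2 * (D + D')
    and the GC drop is exactly the CpG percentage deficit.
    """
    deficit_pct = initial.cpg_percent - observed["CG"]  # CpG%_ini - CpG%_obs
    if stats is None:
        h_per_dinuc = deficit_pct / 100.0
        ratio_n_over_l = 1.0
        H = h_per_dinuc  # per-dinucleotide budget; absolute H undefined without L
    else:
        H = mutation_budget(initial, observed, stats)
        h_per_dinuc = H / stats.n_dinucleotides if stats.n_dinucleotides else 0.0
        ratio_n_over_l = stats.n_dinucleotides / stats.L if stats.L else 1.0
    if deficit_pct < 0 and stats is None:
        warnings.warn(
            "observed CpG exceeds the assumed initial CpG; the model premise is violated",
            stacklevel=2,
        )

    shift = matrix_D(params) + matrix_Dprime(params)
    expected = {
        d: initial.profile[d] + 100.0 * (h_per_dinuc / 2.0) * shift[d]
        for d in DINUCLEOTIDES
    }
    gc_exp = initial.gc_ini - 100.0 * h_per_dinuc * ratio_n_over_l
    profile = DinucleotideProfile(proportions=expected, gc_percent=gc_exp, source="expected")

    if h_per_dinuc == 0.0:
        trends = {cls: TREND_UNCHANGED for cls in POOLED_CLASSES}
    else:
        trends = trend_table(params)
    return PredictionResult(H=H, expected=profile, trends=trends, gc_exp=gc_exp)


def predict_from_summary(
    gc_ini: float,
    cpg_obs_percent: float,
    params: ContextProbabilities,
    gc_obs_percent: float | None = None,
) -> PredictionResult:
    """Run the model from printed composition statistics alone.

    Builds the product-form initial state at ``gc_ini`` and an observed
    profile carrying the stated CpG% (the only observed proportion the
    prediction itself consumes), then predicts in the infinite-genome
    limit.
    """
    init = initial_state(gc_ini)
    rest = (100.0 - cpg_obs_percent) / 15.0
    proportions = {d: (cpg_obs_percent if d == "CG" else rest) for d in DINUCLEOTIDES}
    observed = DinucleotideProfile(
        proportions=proportions,
        gc_percent=gc_obs_percent if gc_obs_percent is not None else 50.0,
        source="observed",
    )
    return predict(init, observed, params, stats=None)
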