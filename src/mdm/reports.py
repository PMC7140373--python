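"""TSV and JSON report writers.

TSV dialect: tab-separated, header row, '.' decimal separator, no
thousands separators.  Proportions and GC are rounded to 2 decimals and
probabilities to 4, matching the conventions of published composition
tables; JSON exports carry full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

from .composition import POOLED_CLASSES, DinucleotideProfile, PooledProfile, pool_profile
from .core import ContextProbabilities, PredictionResult
from .evaluation import EvaluationReport

_POOLED_ORDER = list(POOLED_CLASSES)


def write_profile_tsv(profile: DinucleotideProfile | PooledProfile, path: str | Path) -> None:
    """Pooled-class proportions plus GC in standard column order."""
    pooled = profile if isinstance(profile, PooledProfile) else pool_profile(profile)
    with open(path, "w") as fh:
        fh.write("\t".join(_POOLED_ORDER + ["GC"]) + "\n")
        gc = pooled.gc_percent
        cells = [f"{pooled[c]:.2f}" for c in _POOLED_ORDER]
        cells.append("" if gc is None else f"{gc:.2f}")
        fh.write("\t".join(cells) + "\n")


def write_profile_json(profile: DinucleotideProfile, path: str | Path) -> None:
    payload = {
        "source": profile.source,
        "gc_percent": profile.gc_percent,
        "proportions": dict(profile.proportions),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_params_tsv(params: ContextProbabilities, path: str | Path) -> None:
    """Eight context probabilities, 4 decimals, standard column order."""
    with open(path, "w") as fh:
        fh.write("P_A\tP_C\tP_G\tP_T\tPp_A\tPp_C\tPp_G\tPp_T\n")
        fh.write("\t".join(f"{v:.4f}" for v in params.p + params.pp) + "\n")


def write_prediction_tsv(result: PredictionResult, path: str | Path) -> None:
    pooled = pool_profile(result.expected)
    with open(path, "w") as fh:
        fh.write("\t".join(_POOLED_ORDER + ["GC"]) + "\n")
        fh.write(
            "\t".join([f"{pooled[c]:.2f}" for c in _POOLED_ORDER] + [f"{result.gc_exp:.2f}"])
            + "\n"
        )
        fh.write("\t".join(result.trends[c] for c in _POOLED_ORDER) + "\t\n")


def write_prediction_json(result: PredictionResult, path: str | Path) -> None:
    payload = {
        "H": result.H,
        "gc_exp": result.gc_exp,
        "expected": dict(result.expected.proportions),
        "trends": dict(result.trends),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_evaluation_tsv(
    report: EvaluationReport,
    observed: PooledProfile,
    expected: PooledProfile,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("class\tobserved\texpected\tdelta_percent\ttrend_obs\ttrend_exp\tmatch\n")
        for cls in _POOLED_ORDER:
            delta = report.delta_proportion[cls]
            fh.write(
                "\t".join(
                    [
                        cls,
                        f"{observed[cls]:.2f}",
                        f"{expected[cls]:.2f}",
                        "NA" if delta is None else f"{delta:.2f}",
                        report.trend_obs[cls],
                        report.trend_exp[cls],
                        str(report.trend_match[cls]).lower(),
                    ]
                )
                + "\n"
            )


def read_pooled_tsv(path: str | Path) -> PooledProfile:
    """Read a pooled-class profile TSV (the `write_profile_tsv` layout)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header and one data row")
    header = lines[0].split("\t")
    cells = lines[1].split("\t")
    row = dict(zip(header, cells))
    missing = [c for c in _POOLED_ORDER if c not in row]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = {c: float(row[c]) for c in _POOLED_ORDER}
    gc = float(row["GC"]) if row.get("GC") not in (None, "") else None
    return PooledProfile(values=values, gc_percent=gc, source="observed")


def read_params_tsv(path: str | Path) -> ContextProbabilities:
    """Read a context-probability TSV (the `write_params_tsv` layout)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header and one data row")
    row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
    try:
        return ContextProbabilities(
            pA=float(row["P_A"]),
            pC=float(row["P_C"]),
            pG=float(row["P_G"]),
            pT=float(row["P_T"]),
            ppA=float(row["Pp_A"]),
            ppC=float(row["Pp_C"]),
            ppG=float(row["Pp_G"]),
            ppT=float(row["Pp_T"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing column {exc}") from exc


def write_evaluation_json(report: EvaluationReport, path: str | Path) -> None:
    payload = {
        "delta_proportion": dict(report.delta_proportion),
        "delta_gc": report.delta_gc,
        "trend_obs": dict(report.trend_obs),
        "trend_exp": dict(report.trend_exp),
        "trend_match": dict(report.trend_match),
        "t_stat": report.t_stat,
        "p_value": report.p_value,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
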