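"""Bundled reference tables: published autosomal composition statistics
(pooled dinucleotide proportions and GC content) and trinucleotide-method
context probabilities for 10 vertebrate genomes (8 mammals plus chicken
and zebrafish).  These let the model run end-to-end without downloading
any genome assembly."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import POOLED_CLASSES, PooledProfile
from .core import ContextProbabilities

GENOMES = (
    "cattle",
    "dog",
    "chicken",
    "chimpanzee",
    "zebrafish",
    "human",
    "mouse",
    "baboon",
    "sheep",
    "pig",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("mdm.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_observed_composition() -> pd.DataFrame:
    """Pooled observed proportions (%) and GC content per genome."""
    return _read("observed_composition.tsv").set_index("genome")


def load_context_probabilities() -> pd.DataFrame:
    """Trinucleotide-method context probabilities per genome."""
    return _read("context_probabilities.tsv").set_index("genome")


def observed_profile_for(genome: str) -> PooledProfile:
    """Published pooled observed profile of one genome."""
    df = load_observed_composition()
    if genome not in df.index:
        raise KeyError(f"unknown genome {genome!r}; available: {', '.join(GENOMES)}")
    row = df.loc[genome]
    values = {cls: float(row[cls]) for cls in POOLED_CLASSES}
    return PooledProfile(values=values, gc_percent=float(row["GC"]), source="observed")


def context_probabilities_for(genome: str) -> ContextProbabilities:
    """Published context probabilities of one genome (4-decimal table)."""
    df = load_context_probabilities()
    if genome not in df.index:
        raise KeyError(f"unknown genome {genome!r}; available: {', '.join(GENOMES)}")
    row = df.loc[genome]
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
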