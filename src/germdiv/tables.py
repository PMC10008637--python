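"""Published summary statistics for the 179-accession pepper panel.

These CSVs transcribe the study's printed report tables for the panel of 94
local landraces (LLR) and 85 current breeding lines (CBL): per-trait Shannon
indices and category frequencies for the 22 qualitative traits, per-trait
summary statistics for the 13 quantitative traits, and the per-locus
diversity statistics of the 27 SSR/InDel markers.  They serve two purposes:
worked-example validation of the statistics implemented here, and realistic
parameterisation of the synthetic-data presets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("germdiv.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def qualitative_shannon() -> pd.DataFrame:
    """Per-trait Shannon index by population (columns trait, population, shannon)."""
    return _load("trait_shannon_qualitative.csv")


def qualitative_frequencies() -> pd.DataFrame:
    """Tidy per-category percentages (trait, code, category, llr_pct, cbl_pct)."""
    return _load("trait_freq_qualitative.csv")


def quantitative_summary() -> pd.DataFrame:
    """Quantitative trait table (trait, population, shannon, cv, max, min,
    range, mean, sd)."""
    return _load("trait_summary_quantitative.csv")


def locus_summary(population: str) -> pd.DataFrame:
    """Printed per-locus marker statistics for ``"LLR"`` or ``"CBL"``."""
    pop = population.upper()
    if pop not in {"LLR", "CBL"}:
        raise ValueError("population must be 'LLR' or 'CBL'")
    return _load(f"locus_summary_{pop.lower()}.csv")
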