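"""Phenotypic diversity statistics for germplasm characterisation.

Qualitative traits are summarised by category frequencies and the Shannon
diversity index H' = -sum(p_i ln p_i) (natural log).  Quantitative traits are
first converted to a 1-10 score relative to the pooled mean M and sample
standard deviation S of the whole panel:

* score 1  : x <  M - 2S
* score 10 : x >= M + 2S
* scores 2-9 : consecutive half-S intervals in between, left-closed.

H' for a quantitative trait is then the Shannon index of the score
frequencies, while Max/Min/Range/Mean/SD/CV (CV = SD/Mean x 100%) are computed
from the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EmptyTraitError(ValueError):
    """All values missing for a trait."""


class DegenerateTraitError(ValueError):
    """A quantitative trait cannot be scored (S = 0) or CV is undefined."""


# ---------------------------------------------------------------------------
# frequencies and Shannon index
# ---------------------------------------------------------------------------

def category_frequencies(values) -> pd.Series:
    """Frequencies of category codes over non-missing values (sum to 1)."""
    s = pd.Series(values).dropna()
    if s.empty:
        raise EmptyTraitError("no non-missing values")
    counts = s.value_counts().sort_index()
    return counts / counts.sum()


def shannon_index(freqs) -> float:
    """Shannon diversity H' = -sum(p ln p) in nats, with 0 ln 0 := 0."""
    p = np.asarray(pd.Series(freqs).to_numpy(), dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequency")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {total}, expected 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# 1-10 scoring of quantitative traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Pooled mean and sample SD defining the 10-score partition."""

    M: float
    S: float

    def __post_init__(self):
        if not np.isfinite(self.M) or not np.isfinite(self.S) or self.S < 0:
            raise ValueError("M and S must be finite with S >= 0")

    @property
    def edges(self) -> np.ndarray:
        """The nine interior bin edges M-2S, M-1.5S, ..., M+2S."""
        return self.M + self.S * (np.arange(9) * 0.5 - 2.0)


def scheme_from_values(values) -> ScoringScheme:
    """Scheme from the aggregate (pooled) data for one trait."""
    x = pd.Series(values).dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise EmptyTraitError("need >= 2 values to set a scoring scheme")
    return ScoringScheme(M=float(x.mean()), S=float(x.std(ddof=1)))


def score_quantitative(values, scheme: ScoringScheme) -> pd.Series:
    """Map raw values to scores 1-10; missing values stay missing."""
    if scheme.S == 0:
        raise DegenerateTraitError("S = 0: identical values cannot be scored")
    s = pd.Series(values, dtype=float)
    x = s.to_numpy()
    # side='right' makes bins left-closed: x == edge goes to the upper score
    scores = np.searchsorted(scheme.edges, x, side="right") + 1
    out = pd.Series(scores, index=s.index, dtype="Int64")
    out[s.isna()] = pd.NA
    return out


# ---------------------------------------------------------------------------
# per-trait summaries
# ---------------------------------------------------------------------------

@dataclass
class TraitDiversitySummary:
    """One row of a trait-diversity report table."""

    trait: str
    kind: str                      # "qualitative" | "quantitative"
    frequencies: pd.Series         # per category code or per score
    shannon: float
    n: int
    n_dropped: int = 0
    stats: dict = field(default_factory=dict)  # Max/Min/Range/Mean/SD/CV


def qualitative_trait_summary(trait: str, values) -> TraitDiversitySummary:
    s = pd.Series(values)
    freqs = category_frequencies(s)
    return TraitDiversitySummary(
        trait=trait,
        kind="qualitative",
        frequencies=freqs,
        shannon=shannon_index(freqs),
        n=int(s.notna().sum()),
        n_dropped=int(s.isna().sum()),
    )


def quantitative_trait_summary(
    trait: str, values, scheme: ScoringScheme
) -> TraitDiversitySummary:
    s = pd.Series(values, dtype=float)
    x = s.dropna().to_numpy()
    if x.size < 2:
        raise EmptyTraitError(f"{trait}: need >= 2 non-missing values")
    scores = score_quantitative(s, scheme)
    freqs = category_frequencies(scores)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0:
        raise DegenerateTraitError(f"{trait}: mean 0, CV undefined")
    stats = {
        "Max": float(x.max()),
        "Min": float(x.min()),
        "Range": float(x.max() - x.min()),
        "Mean": mean,
        "SD": sd,
        "CV": sd / mean * 100.0,
    }
    return TraitDiversitySummary(
        trait=trait,
        kind="quantitative",
        frequencies=freqs,
        shannon=shannon_index(freqs),
        n=int(x.size),
        n_dropped=int(s.isna().sum()),
        stats=stats,
    )


# ---------------------------------------------------------------------------
# two-population comparison
# ---------------------------------------------------------------------------

def compare_populations(
    a: TraitDiversitySummary, b: TraitDiversitySummary
) -> dict:
    """Per-trait differences A - B (Shannon, frequencies, summary stats)."""
    if a.trait != b.trait or a.kind != b.kind:
        raise ValueError(f"cannot compare {a.trait!r}/{a.kind} with {b.trait!r}/{b.kind}")
    cats = a.frequencies.index.union(b.frequencies.index)
    fa = a.frequencies.reindex(cats, fill_value=0.0)
    fb = b.frequencies.reindex(cats, fill_value=0.0)
    diff = {
        "trait": a.trait,
        "shannon_diff": a.shannon - b.shannon,
        "frequency_diff": fa - fb,
    }
    if a.stats and b.stats:
        diff["stats_diff"] = {k: a.stats[k] - b.stats[k] for k in a.stats}
    return diff


def panel_summaries(trait_table, population: str | None = None):
    """Summaries for every trait in a :class:`~germdiv.data_model.TraitTable`.

    Quantitative scoring schemes are always set from the aggregate data
    (both populations pooled), so populations are scored on a common scale.
    """
    qual, quant = trait_table.qualitative, trait_table.quantitative
    mask = (
        trait_table.populations == population
        if population is not None
        else pd.Series(True, index=qual.index)
    )
    out = {}
    for c in qual.columns:
        out[c] = qualitative_trait_summary(c, qual.loc[mask, c])
    for c in quant.columns:
        scheme = scheme_from_values(quant[c])  # pooled over the whole panel
        out[c] = quantitative_trait_summary(c, quant.loc[mask, c], scheme)
    return out
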