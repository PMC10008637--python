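"""Per-locus diversity statistics for codominant SSR/InDel markers.

For a locus with allele frequencies p_1..p_k estimated from the observed
allele copies:

* gene diversity (expected heterozygosity)  D = 1 - sum(p_i^2)
* observed heterozygosity                   H = fraction of heterozygous calls
* polymorphism information content (Botstein et al.)
  PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

Frequencies are the uncorrected sample proportions (no small-sample
correction), computed within the selected population only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data_model import MISSING, GenotypeMatrix


class EmptyLocusError(ValueError):
    """No non-missing calls at a locus."""


@dataclass(frozen=True)
class AlleleFrequencies:
    locus: str
    frequencies: dict       # allele code -> proportion of observed copies
    n_obs: int              # accessions with a non-missing call


@dataclass(frozen=True)
class LocusSummary:
    """One locus row of a marker-diversity report table."""

    marker: str
    major_allele_frequency: float
    genotype_no: int
    sample_size: int
    n_obs: int
    allele_no: int
    gene_diversity: float
    heterozygosity: float
    pic: float


def allele_frequencies(gm: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Allele frequencies over the 2 x n_obs observed copies at one locus."""
    j = gm.loci.index(locus)
    col = gm.calls[:, j, :]
    obs = col[col[:, 0] != MISSING]
    if obs.size == 0:
        raise EmptyLocusError(locus)
    alleles, counts = np.unique(obs.ravel(), return_counts=True)
    freqs = {int(a): float(c) / obs.size for a, c in zip(alleles, counts)}
    return AlleleFrequencies(locus=locus, frequencies=freqs, n_obs=len(obs))


def gene_diversity(p) -> float:
    """1 - sum(p^2) for a frequency vector."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    return float(1.0 - (p ** 2).sum())


def pic(p) -> float:
    """Botstein PIC: 1 - sum(p^2) - [ (sum p^2)^2 - sum p^4 ].

    The bracket equals sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    s2 = (p ** 2).sum()
    s4 = (p ** 4).sum()
    return float(1.0 - s2 - (s2 ** 2 - s4))


def locus_summary(gm: GenotypeMatrix, locus: str) -> LocusSummary:
    """All Table-style columns for one locus."""
    j = gm.loci.index(locus)
    col = gm.calls[:, j, :]
    obs = col[col[:, 0] != MISSING]
    if obs.size == 0:
        raise EmptyLocusError(locus)
    af = allele_frequencies(gm, locus)
    # major-allele ties broken by smallest allele code (dict is code-sorted)
    codes = sorted(af.frequencies)
    freqs = np.array([af.frequencies[c] for c in codes])
    major = float(freqs.max())
    het = float((obs[:, 0] != obs[:, 1]).mean())
    genotypes = {tuple(g) for g in obs}
    return LocusSummary(
        marker=locus,
        major_allele_frequency=major,
        genotype_no=len(genotypes),
        sample_size=gm.n_accessions,
        n_obs=af.n_obs,
        allele_no=len(codes),
        gene_diversity=gene_diversity(freqs),
        heterozygosity=het,
        pic=pic(freqs),
    )


def summarize_panel(gm: GenotypeMatrix, population: str | None = None) -> pd.DataFrame:
    """Per-locus summaries plus a ``Mean`` row and total allele count.

    Returns a DataFrame with one row per locus in input order and a final
    ``Mean`` row; ``df.attrs["total_alleles"]`` holds the summed AlleleNo.
    """
    sub = gm.subset(population=population) if population is not None else gm
    if sub.n_loci == 0:
        raise ValueError("no loci")
    rows = [asdict(locus_summary(sub, locus)) for locus in sub.loci]
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="marker").mean(numeric_only=True)
    mean_row["marker"] = "Mean"
    df = pd.concat([df, mean_row.to_frame().T[df.columns]], ignore_index=True)
    for c in df.columns:
        if c != "marker":
            df[c] = df[c].astype(float)
    df.attrs["total_alleles"] = int(df.loc[df["marker"] != "Mean", "allele_no"].sum())
    return df


def nei_fst(gm: GenotypeMatrix, labels: pd.Series) -> float:
    """Multi-locus G_ST-style divergence: 1 - mean(H_S) / mean(H_T).

    H_S is the mean within-population gene diversity (unweighted over
    populations), H_T the gene diversity of the pooled frequencies; locus
    values are combined by averaging H_S and H_T over loci.
    """
    labels = pd.Series(labels, index=gm.ids)
    pops = sorted(labels.unique())
    hs_vals, ht_vals = [], []
    for locus in gm.loci:
        try:
            pooled = allele_frequencies(gm, locus)
        except EmptyLocusError:
            continue
        codes = sorted(pooled.frequencies)
        per_pop = []
        mean_p = np.zeros(len(codes))
        ok = True
        for pop in pops:
            sub = gm.subset(ids=labels[labels == pop].index)
            try:
                af = allele_frequencies(sub, locus)
            except EmptyLocusError:
                ok = False
                break
            p = np.array([af.frequencies.get(c, 0.0) for c in codes])
            per_pop.append(gene_diversity(p))
            mean_p += p / len(pops)
        if not ok:
            continue
        hs_vals.append(float(np.mean(per_pop)))
        ht_vals.append(gene_diversity(mean_p))
    hs, ht = float(np.mean(hs_vals)), float(np.mean(ht_vals))
    return 0.0 if ht == 0 else 1.0 - hs / ht
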