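"""Synthetic genotype and phenotype panels with known truth.

Genotypes follow the Balding-Nichols construction: each locus draws ancestral
allele frequencies p from a flat Dirichlet, and each of the diverged
populations draws its own frequencies from Dirichlet(p * (1-F)/F), so F
controls the expected divergence (roughly the locus-wise FST).  Pure
individuals sample both allele copies per locus from their population's
frequencies; admixed individuals first draw an ancestry vector Q from a
symmetric Dirichlet and pick the source population per allele copy.  Allele
codes are emitted as plausible fragment sizes (150 + 2*index) so synthetic
files exercise the same parsers as real data.

Phenotypes: categorical traits from per-population frequency vectors,
quantitative traits from per-population normals.

``paperlike_spec`` mirrors the structure of the real pepper panel: 179
accessions (80 landrace-like + 75 breeding-line-like + 24 admixed), 27 loci
with 2-20 alleles, and 22 qualitative + 13 quantitative traits whose
generating frequencies / means are the published panel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .data_model import MISSING, Accession, GenotypeMatrix, TraitTable


class SpecError(ValueError):
    pass


@dataclass
class SimulationSpec:
    pops: tuple = ("P1", "P2")
    n_per_pop: tuple = (50, 50)
    n_admixed: int = 0
    n_loci: int = 20
    alleles_per_locus: tuple = (2, 20)
    fst: float = 0.3
    missing_rate: float = 0.0
    admixture_alpha: float = 0.5
    #: trait name -> {pop: frequency vector over category codes 1..k}
    qual_traits: dict = field(default_factory=dict)
    #: trait name -> {pop: (mean, sd)}
    quant_traits: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.pops) != len(self.n_per_pop):
            raise SpecError("pops and n_per_pop lengths differ")
        if any(n < 0 for n in self.n_per_pop) or self.n_admixed < 0:
            raise SpecError("counts must be >= 0")
        if not 0 < self.fst < 1:
            raise SpecError("F must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SpecError("missing_rate must lie in [0, 1)")
        lo, hi = self.alleles_per_locus
        if lo < 2:
            raise SpecError("polymorphic loci need >= 2 alleles")
        if hi < lo:
            raise SpecError("alleles_per_locus range inverted")
        for name, by_pop in self.qual_traits.items():
            for pop, f in by_pop.items():
                f = np.asarray(f, dtype=float)
                if not np.isclose(f.sum(), 1.0, atol=1e-6):
                    raise SpecError(f"trait {name!r}, pop {pop}: frequencies sum {f.sum()}")


def simulate_genotypes(spec: SimulationSpec):
    """Returns (GenotypeMatrix, true source labels, true Q matrix).

    Pure individuals carry their population name both as accession metadata
    and in the label series; admixed individuals are labelled ``"admixed"``
    in the label series and carry their majority-ancestry population as
    metadata.
    """
    rng = np.random.default_rng(spec.seed)
    npop = len(spec.pops)
    lo, hi = spec.alleles_per_locus
    n = sum(spec.n_per_pop) + spec.n_admixed

    pop_freqs = []  # per locus: (npop, k_l)
    for _ in range(spec.n_loci):
        k = int(rng.integers(lo, hi + 1))
        p_anc = rng.dirichlet(np.ones(k))
        conc = np.clip(p_anc * (1.0 - spec.fst) / spec.fst, 1e-6, None)
        pop_freqs.append(np.vstack([rng.dirichlet(conc) for _ in range(npop)]))

    Q_true = np.zeros((n, npop))
    source = []
    row = 0
    for ip, (pop, size) in enumerate(zip(spec.pops, spec.n_per_pop)):
        Q_true[row : row + size, ip] = 1.0
        source += [pop] * size
        row += size
    if spec.n_admixed:
        Q_true[row:] = rng.dirichlet(
            np.full(npop, spec.admixture_alpha), size=spec.n_admixed
        )
        source += ["admixed"] * spec.n_admixed

    calls = np.empty((n, spec.n_loci, 2), dtype=np.int64)
    cum_q = Q_true.cumsum(axis=1)
    for l, freqs in enumerate(pop_freqs):
        k = freqs.shape[1]
        for c in (0, 1):
            z = (cum_q < rng.random(n)[:, None]).sum(axis=1).clip(max=npop - 1)
            # inverse-CDF draw of alleles, one source row per individual
            u = rng.random(n)
            cum = freqs.cumsum(axis=1)[z]
            a = (cum < u[:, None]).sum(axis=1).clip(max=k - 1)
            calls[:, l, c] = 150 + 2 * a
    if spec.missing_rate > 0:
        drop = rng.random((n, spec.n_loci)) < spec.missing_rate
        calls[drop] = MISSING

    ids, accs = [], []
    counters: dict[str, int] = {}
    for i, src in enumerate(source):
        tag = "ADM" if src == "admixed" else src
        counters[tag] = counters.get(tag, 0) + 1
        acc_id = f"{tag}-{counters[tag]:03d}"
        ids.append(acc_id)
        pop_label = spec.pops[int(Q_true[i].argmax())]
        accs.append(Accession(id=acc_id, population=pop_label, origin="simulated"))
    gm = GenotypeMatrix(accs, [f"SSR{j + 1:02d}" for j in range(spec.n_loci)], calls)
    return gm, pd.Series(source, index=ids, name="source"), Q_true


def simulate_phenotypes(spec: SimulationSpec, populations: pd.Series) -> TraitTable:
    """Trait table for accessions with the given population labels."""
    rng = np.random.default_rng(spec.seed + 1)
    ids = list(populations.index)
    pops = populations.to_numpy()
    qual = {}
    for name, by_pop in spec.qual_traits.items():
        col = np.empty(len(ids), dtype=np.int64)
        for pop in np.unique(pops):
            f = np.asarray(by_pop[pop], dtype=float)
            sel = pops == pop
            col[sel] = rng.choice(np.arange(1, len(f) + 1), size=sel.sum(), p=f / f.sum())
        qual[name] = col
    quant = {}
    for name, by_pop in spec.quant_traits.items():
        col = np.empty(len(ids))
        for pop in np.unique(pops):
            mean, sd = by_pop[pop]
            sel = pops == pop
            col[sel] = rng.normal(mean, sd, size=sel.sum())
        quant[name] = col
    return TraitTable(
        qualitative=pd.DataFrame(qual, index=ids),
        quantitative=pd.DataFrame(quant, index=ids),
        populations=populations.copy(),
    )


def simulate_dataset(spec: SimulationSpec):
    """Genotypes + phenotypes + truth for one spec (single seed)."""
    gm, source, q_true = simulate_genotypes(spec)
    tt = simulate_phenotypes(spec, gm.populations)
    return gm, tt, source, q_true


def paperlike_spec(seed: int = 0) -> SimulationSpec:
    """A spec shaped like the real pepper panel (179 x 27, 35 traits).

    Qualitative category frequencies and quantitative means/SDs are the
    published panel values, so synthetic marginals mirror the real tables.
    """
    qual = {}
    freq = tables.qualitative_frequencies()
    for trait, grp in freq.groupby("trait", sort=False):
        grp = grp.sort_values("code")
        llr = grp["llr_pct"].to_numpy() / 100.0
        cbl = grp["cbl_pct"].to_numpy() / 100.0
        qual[trait] = {"LLR": llr / llr.sum(), "CBL": cbl / cbl.sum()}
    quant = {}
    qs = tables.quantitative_summary()
    for trait, grp in qs.groupby("trait", sort=False):
        quant[trait] = {
            row["population"]: (float(row["mean"]), float(row["sd"]))
            for _, row in grp.iterrows()
        }
    return SimulationSpec(
        pops=("LLR", "CBL"),
        n_per_pop=(80, 75),
        n_admixed=24,
        n_loci=27,
        alleles_per_locus=(2, 20),
        fst=0.25,
        missing_rate=0.02,
        admixture_alpha=0.5,
        qual_traits=qual,
        quant_traits=quant,
        seed=seed,
    )
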