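"""End-to-end pipeline orchestration and report-table writers.

``run_pipeline`` executes the full diversity workflow on a genotype +
phenotype dataset (loaded from files, or the paper-like synthetic preset when
no input paths are given) and writes the report bundle: qualitative and
quantitative trait-diversity tables, per-locus marker statistics per
population, the chord-distance matrix, NJ and UPGMA Newick trees, admixture
Q-matrices with the Evanno table and membership counts, PCoA coordinates and
a run log.  Report tables round the way the field prints them (Shannon and
marker statistics to 2 dp, percentages and CV to 1 dp); full-precision
values are written alongside in ``*_precise.csv`` files.  A rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import platform
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import AdmixtureConfig, assign_groups, evanno_delta_k, structure_scan
from .data_model import GenotypeMatrix, TraitTable, read_genotypes, read_traits, validate_dataset
from .distance_tree import distance_matrix, nj_tree, upgma_tree, write_newick, write_phylip
from .marker_diversity import summarize_panel
from .ordination import pcoa
from .pheno_diversity import compare_populations, panel_summaries
from .synthetic_data import paperlike_spec, simulate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genotypes: str | None = None        # None -> paper-like synthetic preset
    traits: str | None = None
    dialect: str = "delimited"
    outdir: str = "results/pipeline"
    seed: int = 0
    populations: tuple = ()             # () -> all labels found in the data
    run_pheno: bool = True
    run_marker: bool = True
    run_distance: bool = True
    run_tree: bool = True
    run_structure: bool = True
    run_pcoa: bool = True
    chord_scale: str = "cavalli"
    k_min: int = 1
    k_max: int = 5
    structure_runs: int = 4
    structure_iterations: int = 2000
    structure_burnin: int = 500
    q_threshold: float = 0.6
    pcoa_axes: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "populations" in raw:
            raw["populations"] = tuple(raw["populations"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# report table builders
# ---------------------------------------------------------------------------

def qualitative_report(tt: TraitTable, pops) -> pd.DataFrame:
    """Trait x population Shannon indices and category percentages, with a
    difference row per trait when exactly two populations are compared."""
    per_pop = {p: panel_summaries(tt, population=p) for p in pops}
    qual_traits = list(tt.qualitative.columns)
    max_cat = max(
        (int(tt.qualitative[c].max()) for c in qual_traits if tt.qualitative[c].notna().any()),
        default=0,
    )
    rows = []
    for trait in qual_traits:
        for p in pops:
            s = per_pop[p][trait]
            row = {"trait": trait, "population": p, "shannon": s.shannon}
            for cat in range(1, max_cat + 1):
                row[f"cat{cat}_pct"] = 100.0 * float(s.frequencies.get(cat, np.nan))
            rows.append(row)
        if len(pops) == 2:
            d = compare_populations(per_pop[pops[0]][trait], per_pop[pops[1]][trait])
            row = {"trait": trait, "population": "Difference", "shannon": d["shannon_diff"]}
            for cat in range(1, max_cat + 1):
                row[f"cat{cat}_pct"] = 100.0 * float(d["frequency_diff"].get(cat, np.nan))
            rows.append(row)
    return pd.DataFrame(rows)


def quantitative_report(tt: TraitTable, pops) -> pd.DataFrame:
    per_pop = {p: panel_summaries(tt, population=p) for p in pops}
    rows = []
    for trait in tt.quantitative.columns:
        for p in pops:
            s = per_pop[p][trait]
            rows.append(
                {
                    "trait": trait,
                    "population": p,
                    "shannon": s.shannon,
                    "cv": s.stats["CV"],
                    "max": s.stats["Max"],
                    "min": s.stats["Min"],
                    "range": s.stats["Range"],
                    "mean": s.stats["Mean"],
                    "sd": s.stats["SD"],
                }
            )
        if len(pops) == 2:
            d = compare_populations(per_pop[pops[0]][trait], per_pop[pops[1]][trait])
            sd_ = d["stats_diff"]
            rows.append(
                {
                    "trait": trait,
                    "population": "Difference",
                    "shannon": d["shannon_diff"],
                    "cv": sd_["CV"],
                    "max": sd_["Max"],
                    "min": sd_["Min"],
                    "range": sd_["Range"],
                    "mean": sd_["Mean"],
                    "sd": sd_["SD"],
                }
            )
    return pd.DataFrame(rows)


def _round(df: pd.DataFrame, two_dp, one_dp) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if c in two_dp or any(c.startswith(p) for p in two_dp if p.endswith("*")):
            out[c] = out[c].astype(float).round(2)
        elif c in one_dp or c.endswith("_pct"):
            out[c] = out[c].astype(float).round(1)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns {artifact name: path}."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    log: list[str] = [
        f"germdiv {__version__} | python {platform.python_version()} | seed {cfg.seed}"
    ]
    artifacts: dict[str, str] = {}

    # stage timers go to the console; the log file stays bit-stable across reruns
    def stage(name):
        print(f"[germdiv {time.perf_counter() - t0:8.2f}s] {name}", flush=True)
        log.append(f"stage: {name}")

    # ---- load or simulate -------------------------------------------------
    stage("load")
    default_pops = None
    if cfg.genotypes is None:
        spec = paperlike_spec(seed=cfg.seed)
        gm, tt, source, _ = simulate_dataset(spec)
        default_pops = list(spec.pops)
        log.append(
            f"  simulated paper-like panel: {gm.n_accessions} accessions x "
            f"{gm.n_loci} loci, {len(tt.qualitative.columns)} qualitative + "
            f"{len(tt.quantitative.columns)} quantitative traits"
        )
    else:
        try:
            gm = read_genotypes(cfg.genotypes, dialect=cfg.dialect)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        tt = read_traits(cfg.traits) if cfg.traits else None
        log.append(f"  read {gm.n_accessions} accessions x {gm.n_loci} loci")
    issues = validate_dataset(gm, tt)
    for issue in issues:
        log.append(f"  validation: {issue.kind}: {issue.detail}")
    pops = list(cfg.populations) or default_pops or sorted(gm.populations.unique())

    # ---- phenotypic diversity --------------------------------------------
    if cfg.run_pheno and tt is not None:
        stage("pheno-div")
        try:
            qual = qualitative_report(tt, pops)
            quant = quantitative_report(tt, pops)
        except Exception as exc:
            raise PipelineError("pheno-div", str(exc)) from exc
        qual.to_csv(out / "trait_diversity_qualitative_precise.csv", index=False)
        quant.to_csv(out / "trait_diversity_quantitative_precise.csv", index=False)
        _round(qual, {"shannon"}, set()).to_csv(
            out / "trait_diversity_qualitative.csv", index=False
        )
        _round(quant, {"shannon"}, {"cv", "max", "min", "range", "mean", "sd"}).to_csv(
            out / "trait_diversity_quantitative.csv", index=False
        )
        artifacts["trait_qualitative"] = str(out / "trait_diversity_qualitative.csv")
        artifacts["trait_quantitative"] = str(out / "trait_diversity_quantitative.csv")

    # ---- marker diversity -------------------------------------------------
    if cfg.run_marker:
        stage("marker-div")
        for p in pops:
            try:
                df = summarize_panel(gm, population=p)
            except Exception as exc:
                raise PipelineError("marker-div", f"population {p}: {exc}") from exc
            df.to_csv(out / f"locus_summary_{p}_precise.csv", index=False)
            rounded = df.copy()
            for c in ("major_allele_frequency", "gene_diversity", "heterozygosity", "pic"):
                rounded[c] = rounded[c].round(2)
            for c in ("genotype_no", "sample_size", "n_obs", "allele_no"):
                rounded[c] = rounded[c].round(1)
            rounded.to_csv(out / f"locus_summary_{p}.csv", index=False)
            log.append(f"  {p}: total alleles {df.attrs['total_alleles']}")
            artifacts[f"locus_summary_{p}"] = str(out / f"locus_summary_{p}.csv")

    # ---- distances and trees ---------------------------------------------
    dm = None
    if cfg.run_distance or cfg.run_tree or cfg.run_pcoa:
        stage("distance")
        try:
            dm = distance_matrix(gm, scale=cfg.chord_scale)
        except Exception as exc:
            raise PipelineError("distance", str(exc)) from exc
        s = dm.summary()
        log.append(f"  chord distances: min {s['min']:.3f} mean {s['mean']:.3f} max {s['max']:.3f}")
        if cfg.run_distance:
            write_phylip(dm, out / "distances.phy")
            artifacts["distances"] = str(out / "distances.phy")
    if cfg.run_tree:
        stage("tree")
        try:
            write_newick(nj_tree(dm), out / "tree_nj.nwk")
            write_newick(upgma_tree(dm), out / "tree_upgma.nwk")
        except Exception as exc:
            raise PipelineError("tree", str(exc)) from exc
        artifacts["tree_nj"] = str(out / "tree_nj.nwk")
        artifacts["tree_upgma"] = str(out / "tree_upgma.nwk")

    # ---- admixture --------------------------------------------------------
    if cfg.run_structure:
        stage("structure")
        base = AdmixtureConfig(
            K=cfg.k_min,
            iterations=cfg.structure_iterations,
            burnin=cfg.structure_burnin,
            runs=cfg.structure_runs,
            seed=cfg.seed,
        )
        try:
            scan = structure_scan(gm, cfg.k_min, cfg.k_max, base)
            for K, res in scan.items():
                for r, run in enumerate(res.runs):
                    pd.DataFrame(
                        run.Q, index=gm.ids, columns=[f"Q{k + 1}" for k in range(K)]
                    ).to_csv(out / f"structure_q_K{K}_run{r + 1}.csv", index_label="id")
            ev = evanno_delta_k({K: res.ln_pk_values for K, res in scan.items()})
            ev.to_csv(out / "evanno.csv")
            best_k = ev.attrs.get("optimal_k")
            log.append(f"  Evanno optimal K: {best_k}")
            if best_k is not None:
                members = assign_groups(
                    scan[best_k].mean_q(), threshold=cfg.q_threshold, ids=gm.ids
                )
                members.to_csv(out / "membership.csv", index_label="id")
                artifacts["membership"] = str(out / "membership.csv")
        except Exception as exc:
            raise PipelineError("structure", str(exc)) from exc
        artifacts["evanno"] = str(out / "evanno.csv")

    # ---- ordination -------------------------------------------------------
    if cfg.run_pcoa:
        stage("pcoa")
        try:
            res = pcoa(dm, n_axes=cfg.pcoa_axes)
        except Exception as exc:
            raise PipelineError("pcoa", str(exc)) from exc
        coords = res.coordinates.copy()
        coords["population"] = gm.populations
        coords.to_csv(out / "pcoa_coordinates.csv", index_label="id")
        log.append(
            "  PCoA axis proportions: "
            + ", ".join(f"{p:.3f}" for p in res.proportion_explained[: cfg.pcoa_axes])
        )
        artifacts["pcoa"] = str(out / "pcoa_coordinates.csv")

    stage("done")
    (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    cfg_dict = asdict(cfg)
    cfg_dict["populations"] = list(cfg_dict["populations"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict), encoding="utf-8")
    artifacts["run_log"] = str(out / "run_log.txt")
    return artifacts
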