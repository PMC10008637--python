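"""Bayesian admixture-model clustering with a Gibbs sampler, plus Evanno's
delta-K model choice and Q-threshold group assignment.

The model is the no-admixture-prior-free ("admixture") mixture model familiar
from Bayesian population assignment: each individual i has a proportion
vector Q_i over K clusters, each cluster k has per-locus allele frequencies
P_k,l, loci are independent and within-cluster genotypes are in
Hardy-Weinberg proportions.  The sampler sweeps:

1. allele-copy origins        Z_ilc | Q, P   (categorical)
2. cluster allele frequencies P | Z          ~ Dirichlet(lambda + counts)
3. admixture proportions      Q_i | Z        ~ Dirichlet(alpha + copy counts)
4. the concentration alpha by random-walk Metropolis (uniform prior on (0,10])

Allele frequencies use an independent Dirichlet(lambda) prior per cluster
(no correlated-frequencies F-model).  ln Pr(X|K) is estimated from the
post-burn-in per-sweep log-likelihood trace as mean - var/2, the estimator
the classic implementation prints, and Evanno's delta-K is computed from
several independent runs per K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np
import pandas as pd

from .data_model import GenotypeMatrix


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AdmixtureConfig:
    """MCMC settings.  Defaults are desk-scale; the published protocol
    (100,000 sweeps, 30,000 burn-in, 8 runs, K = 1..10) is reachable by
    overriding them."""

    K: int
    iterations: int = 5000
    burnin: int = 1000
    runs: int = 4
    seed: int = 0
    lam: float = 1.0        # Dirichlet prior for allele frequencies
    alpha0: float = 1.0     # initial admixture concentration
    alpha_step: float = 0.05
    alpha_max: float = 10.0

    def __post_init__(self):
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if not 0 <= self.burnin < self.iterations:
            raise ConfigError("need 0 <= burnin < iterations")
        if self.runs < 1 or self.lam <= 0 or self.alpha0 <= 0:
            raise ConfigError("runs >= 1, lambda > 0, alpha0 > 0 required")


@dataclass
class RunResult:
    Q: np.ndarray           # (n, K) posterior-mean admixture proportions
    alpha_trace: np.ndarray
    lnl_trace: np.ndarray   # post-burn-in per-sweep log-likelihood
    ln_pk: float            # mean(lnL) - var(lnL)/2


@dataclass
class StructureResult:
    config: AdmixtureConfig
    ids: list
    runs: list[RunResult] = field(default_factory=list)

    @property
    def ln_pk_values(self) -> list[float]:
        return [r.ln_pk for r in self.runs]

    def mean_q(self) -> np.ndarray:
        aligned, mean_q = align_runs([r.Q for r in self.runs])
        return mean_q


def _encode(gm: GenotypeMatrix):
    """Map allele codes to 0..k_l-1 per locus; missing -> -1.  All-missing
    loci are excluded."""
    from .data_model import MISSING

    codes = np.full(gm.calls.shape, -1, dtype=np.int64)
    n_alleles, keep = [], []
    for j in range(gm.n_loci):
        col = gm.calls[:, j, :]
        obs = col[:, 0] != MISSING
        uniq = np.unique(col[obs])
        if uniq.size == 0:
            continue
        keep.append(j)
        lut = {c: i for i, c in enumerate(uniq)}
        for c in (0, 1):
            codes[obs, j, c] = [lut[v] for v in col[obs, c]]
        n_alleles.append(uniq.size)
    return codes[:, keep, :], np.array(n_alleles)


def _log_dirichlet_symm(q: np.ndarray, alpha: float) -> float:
    """Sum of log Dirichlet(alpha * 1_K) densities over the rows of q."""
    from scipy.special import gammaln

    n, K = q.shape
    return float(
        n * (gammaln(K * alpha) - K * gammaln(alpha))
        + (alpha - 1.0) * np.log(np.clip(q, 1e-300, None)).sum()
    )


def _gibbs(codes, n_alleles, cfg: AdmixtureConfig, rng: np.random.Generator) -> RunResult:
    n, L, _ = codes.shape
    K = cfg.K
    kmax = int(n_alleles.max())
    valid = np.zeros((L, kmax), dtype=bool)
    for l, k_l in enumerate(n_alleles):
        valid[l, :k_l] = True
    obs = codes[:, :, 0] >= 0                     # (n, L)
    obs_idx = [np.nonzero(obs[:, l])[0] for l in range(L)]

    Q = rng.dirichlet(np.ones(K), size=n)
    alpha = cfg.alpha0
    Z = np.where(codes >= 0, rng.integers(0, K, size=codes.shape), -1)

    alpha_trace = np.empty(cfg.iterations)
    lnl_trace = []
    q_sum = np.zeros((n, K))
    n_kept = 0

    for sweep in range(cfg.iterations):
        # (2) P | Z
        counts = np.zeros((K, L, kmax))
        for c in (0, 1):
            for l in range(L):
                idx = obs_idx[l]
                np.add.at(counts, (Z[idx, l, c], l, codes[idx, l, c]), 1.0)
        shape = np.where(valid, cfg.lam + counts, 0.0)
        P = rng.gamma(shape)
        P = np.where(valid, P, 0.0)
        P /= np.clip(P.sum(axis=2, keepdims=True), 1e-300, None)

        # (1) Z | Q, P
        qcounts = np.zeros((n, K))
        for l in range(L):
            idx = obs_idx[l]
            for c in (0, 1):
                a = codes[idx, l, c]
                W = Q[idx] * P[:, l, a].T            # (n_obs, K)
                W /= W.sum(axis=1, keepdims=True)
                u = rng.random(idx.size)
                z = (W.cumsum(axis=1) < u[:, None]).sum(axis=1)
                Z[idx, l, c] = z
                np.add.at(qcounts, (idx, z), 1.0)

        # (3) Q | Z
        G = rng.gamma(alpha + qcounts)
        Q = G / np.clip(G.sum(axis=1, keepdims=True), 1e-300, None)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        # (4) alpha by reflected random-walk Metropolis (only meaningful K > 1)
        if K > 1:
            prop = alpha + rng.normal(0.0, cfg.alpha_step)
            if prop <= 0:
                prop = -prop
            if prop > cfg.alpha_max:
                prop = 2 * cfg.alpha_max - prop
            if 0 < prop <= cfg.alpha_max:
                delta = _log_dirichlet_symm(Q, prop) - _log_dirichlet_symm(Q, alpha)
                if np.log(rng.random()) < delta:
                    alpha = prop
        alpha_trace[sweep] = alpha

        if sweep >= cfg.burnin:
            lnl = 0.0
            for l in range(L):
                idx = obs_idx[l]
                for c in (0, 1):
                    a = codes[idx, l, c]
                    lik = (Q[idx] * P[:, l, a].T).sum(axis=1)
                    lnl += float(np.log(np.clip(lik, 1e-300, None)).sum())
            lnl_trace.append(lnl)
            q_sum += Q
            n_kept += 1

    lnl_trace = np.array(lnl_trace)
    ln_pk = float(lnl_trace.mean() - lnl_trace.var(ddof=0) / 2.0)
    return RunResult(
        Q=q_sum / n_kept,
        alpha_trace=alpha_trace,
        lnl_trace=lnl_trace,
        ln_pk=ln_pk,
    )


def run_admixture(gm: GenotypeMatrix, cfg: AdmixtureConfig) -> StructureResult:
    """Independent chains for one K; run r is seeded ``seed + 1000*K + r``."""
    codes, n_alleles = _encode(gm)
    if gm.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    result = StructureResult(config=cfg, ids=gm.ids)
    for r in range(cfg.runs):
        rng = np.random.default_rng(cfg.seed + 1000 * cfg.K + r)
        result.runs.append(_gibbs(codes, n_alleles, cfg, rng))
    return result


def structure_scan(
    gm: GenotypeMatrix, k_min: int, k_max: int, base: AdmixtureConfig
) -> dict[int, StructureResult]:
    """run_admixture for each K in [k_min, k_max] with shared base settings."""
    return {
        K: run_admixture(gm, replace(base, K=K)) for K in range(k_min, k_max + 1)
    }


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(ln_pk: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table from per-K, per-run ln Pr(X|K) estimates.

    Columns: ``mean_lnpk``, ``sd_lnpk``, ``lprime`` (first difference),
    ``labs`` (|second difference|), ``delta_k``.  delta_k is defined only for
    interior K with sd > 0; elsewhere NaN.  ``df.attrs['optimal_k']`` holds
    argmax delta_k.
    """
    ks = sorted(ln_pk)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if any(len(ln_pk[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(ln_pk[k])) for k in ks}
    sd = {k: float(np.std(ln_pk[k], ddof=1)) for k in ks}
    lprime = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    labs = {k: abs(lprime[k + 1] - lprime[k]) for k in ks[1:-1]}
    rows = []
    for k in ks:
        dk = np.nan
        if k in labs:
            dk = labs[k] / sd[k] if sd[k] > 0 else np.nan
        rows.append(
            {
                "K": k,
                "mean_lnpk": mean[k],
                "sd_lnpk": sd[k],
                "lprime": lprime.get(k, np.nan),
                "labs": labs.get(k, np.nan),
                "delta_k": dk,
            }
        )
    df = pd.DataFrame(rows).set_index("K")
    if df["delta_k"].notna().any():
        df.attrs["optimal_k"] = int(df["delta_k"].idxmax())
    return df


# ---------------------------------------------------------------------------
# run alignment and group assignment
# ---------------------------------------------------------------------------

def align_runs(q_runs: list[np.ndarray]):
    """Greedy column-permutation alignment of each run to the first.

    Clusters of run r are matched to clusters of run 0 by repeatedly pairing
    the columns with the largest remaining inner product.  Returns the
    aligned runs and their element-wise mean.
    """
    if not q_runs:
        raise ValueError("no runs")
    K = q_runs[0].shape[1]
    if any(q.shape != q_runs[0].shape for q in q_runs):
        raise ValueError("runs differ in shape (same K required)")
    ref = q_runs[0]
    aligned = [ref]
    for q in q_runs[1:]:
        score = ref.T @ q                    # (K_ref, K_run)
        perm = [-1] * K
        used_r, used_c = set(), set()
        for _ in range(K):
            best = None
            for a in range(K):
                if a in used_r:
                    continue
                for b in range(K):
                    if b in used_c:
                        continue
                    if best is None or score[a, b] > best[0]:
                        best = (score[a, b], a, b)
            _, a, b = best
            perm[a] = b
            used_r.add(a)
            used_c.add(b)
        aligned.append(q[:, perm])
    return aligned, np.mean(aligned, axis=0)


def best_permutation(q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Exhaustive best column permutation of ``q`` against ``ref`` (small K)."""
    K = q.shape[1]
    best, best_perm = -np.inf, None
    for perm in permutations(range(K)):
        s = float((ref * q[:, perm]).sum())
        if s > best:
            best, best_perm = s, perm
    return q[:, list(best_perm)]


def assign_groups(Q: np.ndarray, threshold: float = 0.6, ids=None) -> pd.DataFrame:
    """Hard assignment to the argmax cluster with an admixed flag.

    An accession is flagged admixed when its maximum Q does not exceed the
    threshold (the membership cut applied when counting well-assigned lines).
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    cluster = Q.argmax(axis=1)
    maxq = Q.max(axis=1)
    df = pd.DataFrame(
        {
            "cluster": cluster + 1,
            "max_q": maxq,
            "admixed": maxq <= threshold,
        },
        index=ids if ids is not None else range(len(Q)),
    )
    counts = (
        df.groupby("cluster")["admixed"]
        .agg(total="size", admixed="sum")
        .assign(assigned=lambda t: t["total"] - t["admixed"])
    )
    df.attrs["membership_counts"] = counts
    return df
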