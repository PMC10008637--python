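# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix.

## Phenotypic diversity

Qualitative traits are integer category codes; frequencies are computed over
non-missing values (missing values are dropped per trait and the drop count
recorded on the summary). The Shannon index uses the natural logarithm,
H′ = −Σ Pᵢ ln Pᵢ with 0·ln 0 := 0, and is reported to 2 dp only at the
reporting layer — never rounded inside a computation.

Quantitative traits are scored 1–10 before H′ is computed. The scoring
scheme uses the mean *M* and the **sample** standard deviation *S* (n−1
denominator) of the **aggregate** data — both populations pooled — so the
two populations are scored on one common scale; this pooling is the reading
adopted for the published protocol, which bases scores on "the aggregate
data", and it is what makes ΔH′ between populations interpretable. Bins are
left-closed/right-open: score 1 iff x < M−2S, score 10 iff x ≥ M+2S (the
boundary belongs to 10), and scores 2–9 occupy consecutive 0.5·S intervals,
so x = M falls on the 5/6 edge and receives score 6. CV = SD/mean × 100 is
computed from raw values, not scores, and is undefined (an error) when the
mean is zero.

## Marker diversity

Allele frequencies are sample proportions over the 2·n_obs observed allele
copies at a locus, computed within the selected population only (the two
populations are summarised separately). Gene diversity is the uncorrected
1 − Σp̂² — no n/(n−1) small-sample correction — matching the magnitudes the
common SSR software prints; PIC uses the Botstein formula via the algebraic
identity Σᵢ<ⱼ2pᵢ²pⱼ² = (Σp²)² − Σp⁴ (verified against a double-loop oracle
in the tests). Genotype counts are distinct unordered allele pairs among
non-missing calls; major-allele ties break to the smallest allele code so
reports are deterministic. The panel summary appends a `Mean` row and
records the summed allele count.

`nei_fst` is a Nei-style G_ST (1 − mean H_S / mean H_T with unweighted
population means and H_S, H_T averaged over loci before the ratio). It
exists to validate the generator's divergence dial, not as a full
Weir–Cockerham estimator.

## Chord distances

Individuals are treated as allele-frequency profiles with entries 0, ½, 1.
Per locus, d = (2/π)·√(2(1 − Σₐ√(xₐyₐ))); the overall distance is the mean
over loci where both individuals are scored (missing loci are skipped
pairwise, and the shared-locus count is kept on the matrix). The 2/π
prefactor gives a single-locus maximum of 2√2/π ≈ 0.9003, consistent with
the 0.04–0.90 range published for the real panel; because distance software
differs in this normalisation, the prefactor (`scale="cavalli"|"none"`) and
the aggregation (`agg="mean"|"sum"`) are isolated behind keyword arguments.

## Trees

NJ is the Saitou–Nei algorithm, hand-implemented for two reasons: ties in
the Q-criterion are broken by the lowest (row, col) index pair, and negative
branch lengths are clamped to zero — both needed for deterministic,
presentable output. Correctness is property-tested (exact recovery of
random additive matrices up to 12 leaves) and cross-checked against
scikit-bio's independent NJ on noisy matrices. UPGMA delegates to SciPy's
average-linkage agglomeration; merge heights are halved pairwise distances,
so the output is rooted, binary and ultrametric (asserted to 1e−9 in
tests). Both trees serialise to Newick via dendropy with 6-significant-digit
branch lengths.

## Admixture model

The sampler implements the classic admixture mixture model: clusters in
Hardy–Weinberg equilibrium, independent loci, an **independent**
Dirichlet(λ = 1) prior per cluster and locus for allele frequencies — not
the correlated-frequencies F-model; that model is deliberately out of scope,
and the simpler prior suffices for ΔK-based K selection on diverged
populations. One sweep updates: allele-copy origins Z (categorical, given Q
and P), P | Z ~ Dirichlet(λ + counts), Qᵢ | Z ~ Dirichlet(α + copy counts),
and α by a reflected Gaussian random-walk Metropolis step (step 0.05,
uniform prior on (0, 10]). Missing allele copies are skipped everywhere;
all-missing loci are excluded up front. The per-sweep log-likelihood is
Σ ln Σₖ q_ik p_k,l,a over non-missing copies, and
ln Pr(X|K) = mean(lnL) − var(lnL)/2 over all post-burn-in sweeps (no
thinning: with sweeps this cheap the full trace is kept). Q is reported as
the posterior mean over post-burn-in sweeps.

Defaults are desk-scale — 5,000 sweeps, 1,000 burn-in, 4 runs — with the
published protocol (100,000 iterations, 30,000 burn-in, 8 runs, K = 1–10)
reachable through the config. Run r at a given K is seeded
`seed + 1000·K + r`, making every chain independently reproducible. Label
switching across chains is resolved by greedy column matching to the first
run (largest remaining inner product first), which the tests show equals
the exhaustive best permutation at K = 2; the full CLUMPP machinery is not
implemented.

Evanno's ΔK follows the original definition: L(K) and its sample SD over
runs, L′(K) = L(K) − L(K−1), |L″(K)| = |L′(K+1) − L′(K)|, and
ΔK = |L″(K)|/s[L(K)] for interior K; ΔK at a K with zero run-to-run SD is
reported as undefined rather than fabricated. Note ΔK is only defined for
interior K, so a structure scan must cover at least three consecutive K
values with at least two runs each.

## Ordination

PCoA uses the Gower construction B = −½ J D² J, an eigendecomposition, and
coordinates Vₖ√λₖ for positive eigenvalues. Chord-mean matrices need not be
Euclidean-embeddable; negative eigenvalues are dropped and their total
magnitude reported on the result (no Lingoes/Cailliez correction — the
simplest defensible convention, made visible rather than hidden). Axis
signs are fixed by making the first non-negligible loading positive, so
exports are reproducible. Correctness is checked by exact reconstruction of
Euclidean configurations and against scikit-bio's PCoA.

## Synthetic data

The generator is first-class, tested code; it defines the conditions under
which the stochastic parts of the pipeline are validated.

Genotypes follow the Balding–Nichols construction: ancestral frequencies
per locus from a flat Dirichlet over k alleles (k uniform on the configured
range), population frequencies from Dirichlet(p_anc·(1−F)/F) so the
divergence dial F approximates the expected locus-wise FST, two allele
copies per individual per locus, admixed individuals with ancestry rows
from a symmetric Dirichlet(α) choosing the source population per copy, and
uniform masking at the missing rate. Allele codes are emitted as plausible
fragment sizes (150 + 2·index) so synthetic files exercise the same parsers
as real data.

The `paperlike` preset mirrors the real panel's structure: 179 accessions
(80 landrace-like + 75 breeding-line-like + 24 admixed ≈ 13%, matching the
published share of lines below the Q = 0.6 membership cut), 27 loci with
2–20 alleles, F = 0.25 (a between-population divergence strong enough to
produce the clean two-cluster structure the real panel shows), 2% missing
calls, and trait generators parameterised directly by the published
category frequencies and means/SDs, so synthetic phenotype marginals mirror
the published tables.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: inbreeding (individuals are Hardy–Weinberg draws,
so synthetic observed heterozygosity is near gene diversity, whereas the
real landraces and inbred breeding lines show Ho far below He); the
asymmetry in allele richness between the two real populations; linkage
between loci; and stepwise SSR mutation structure. Tests against synthetic
data validate the estimators and the recovery machinery, not those
biological features.

## Problem sizes and numerical conventions

Stochastic validation runs use deliberately modest sizes chosen as the
package's own test conditions: two populations of 50, 20 loci, F = 0.3 for
admixture recovery; K ∈ {1..5} with 3–4 chains of ~800–1,200 sweeps for ΔK
(the ΔK peak at the true K is large — two orders of magnitude above the
off-peak values — so short chains suffice); random additive trees up to 12
leaves for NJ consistency. Tolerances: simplex sums to 1e−9; ultrametricity
to 1e−9; PCoA reconstruction to 1e−9; sampling-based checks use 4-SE
binomial bands. Degenerate inputs fail loudly: empty traits, zero-SD
scoring schemes, zero-mean CV, all-missing loci, incomparable accession
pairs and invalid (asymmetric, NaN) distance matrices all raise typed
errors rather than producing numbers.

## Known limitations

* The correlated-allele-frequencies prior, linkage model and prior
  population information of the classic structure software are not
  implemented; exact reproduction of the published Pop1 = 70 / Pop2 = 109
  split would additionally require the unpublished supplementary genotype
  table, so that split is treated as a qualitative two-cluster check.
* Chord-distance normalisation across SSR software is not standardised; the
  published mean distance of 0.50 for the real panel may depend on the
  alternative scaling, which is why the prefactor is switchable.
* No significance testing of ΔH′ between populations is provided (none is
  defined for the published comparison), and no bootstrap support values on
  trees.
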