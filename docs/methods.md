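# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `eurostruct`. Symbols: K populations, dosage d ∈ {0,1,2}
counting the A1/"alt" allele, pᵢⱼ the frequency of allele j in population i,
p̄ⱼ its unweighted mean over populations.

## Genotype PCA and Tracy–Widom significance

Standardization follows the classical eigenanalysis recipe for SNP data:
per SNP, missing dosages are imputed to the SNP mean, the column is
centred, and divided by √(p̂(1−p̂)) with the posterior (add-one) frequency
estimate p̂ = (1 + Σd)/(2 + 2·n_called). The posterior estimate keeps the
denominator away from zero at rare alleles; a plain sample-frequency
variant is available (`freq_estimate="plain"`), under which monomorphic
columns are zeroed. Scores and loadings come from the eigendecomposition of
the sample covariance X Xᵀ/n_snps (equivalently a thin SVD); the sign of
each component is fixed so its largest-magnitude score is positive, making
runs reproducible.

Component significance uses the successive-eigenvalue Tracy–Widom test: for
component k the eigenvalues below it are treated as a fresh null spectrum
of m values with sums S₁, S₂; the effective marker count is the moment
estimate n′ = (m+1)S₁²/(mS₂ − S₁²) (derived by matching E[S₁²/S₂] for a
white Wishart; degenerate spectra fall back to the true marker count); the
top remaining eigenvalue, normalized as ℓ = m·λ/S₁, is centred and scaled
by μ = (√(n′−1)+√m)²/n′ and σ = (√(n′−1)+√m)/n′ · (1/√(n′−1)+1/√m)^{1/3}
and referred to TW₁.

TW₁ tail probabilities use the shifted-Gamma closed form (Chiani 2014):
TW₁ ≈ Γ(k=46.44605, θ=0.18605) − 9.84801, accurate to ~10⁻⁴ in CDF across
the support. This replaces the traditional interpolated quantile table: it
is smooth, needs no shipped data, and never extrapolates; p-values are
clipped to [10⁻³⁰⁰, 1]. Calibration is verified in the test suite: on
i.i.d. noise the top-eigenvalue p-value exceeds 0.01 in ≥18/20 replicates,
and classical reference quantiles (p=0.05 at 0.979, p=0.01 at 2.023) are
reproduced.

## Geographic concordance

Population centroids are the arithmetic means of sample scores. Geography
is projected to local planar km by an equirectangular projection about the
panel centroid (distance distortion <1% at the continental scale used);
great-circle distances use the haversine formula with R = 6371 km.

* Spearman correlations of a PC against latitude or longitude use an exact
  permutation null for ≤8 populations (the t-approximation is poor at
  these sample sizes) and the asymptotic p otherwise.
* The best-alignment bearing grid-searches θ ∈ {−90°, −89.5°, …, 89.5°}
  (0.5° steps, matching the integer-degree resolution one would report),
  projecting centroids onto the axis y·cosθ + x·sinθ and maximizing
  |Spearman ρ|; ties resolve toward smaller |θ|. Because the criterion is a
  rank correlation, configurations with a clean monotone gradient produce a
  plateau of equally good bearings; the reported angle is the plateau point
  closest to north.
* The Mantel test correlates off-diagonal upper-triangle entries (Pearson
  by default, Spearman behind a flag) and permutes one joint row/column
  relabeling per iteration; p uses the add-one formula
  (1 + #{r* ≥ r})/(1 + n_perm), so p is never 0 and its minimum at 1000
  permutations is 1/1001. An exact mode enumerates all n! relabelings for
  n ≤ 8.
* The Procrustes test centres and scales both configurations to unit sum
  of squares, takes the optimal rotation from the SVD of YᵀX, and reports
  t = √(1−m²). Reflections are disallowed by default (geographic
  orientation is meaningful); `allow_reflection=True` recovers the
  unconstrained statistic (verified against `scipy.spatial.procrustes`).

## Pairwise Fst and the indistinct threshold

The Hudson estimator is computed as a ratio of averages across SNPs:
numerator (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1) with n in allele counts
(the finite-sample correction), denominator p₁q₂ + p₂q₁. Ratio-of-averages
is nearly unbiased in the Fst ≲ 0.01 regime this package targets; estimates
for indistinguishable pairs may be slightly negative and are reported
unclipped, so the strict `Fst < 0.001` indistinct rule behaves sensibly.
A Weir–Cockerham variant (allele-count-only, HWE heterozygosity) is
available for sensitivity. Under the Balding–Nichols generator the
estimator's expectation for populations with parameters F₁, F₂ is
(F₁+F₂)/2 (from Var(pᵢ) = Fᵢ·p₀q₀ and E[p₁q₂+p₂q₁] = 2p₀q₀), which is what
the parameter-recovery tests assert.

`indistinct_groups` returns both the raw set of below-threshold pairs —
used for assignment scoring, since indistinctness is not transitive — and
the transitive closure as a diagnostic.

## AIM and PCAIM selection

Informativeness is computed in nats with 0·ln 0 = 0 and the unweighted mean
p̄ⱼ over populations (hence the harmonized 70-per-population reference: an
unweighted mean over unequal panels would bias scores toward large
cohorts). It is 0 iff all populations share a frequency and bounded by
ln K. The mean-MAF filter averages the consistently labelled alt allele
across populations *before* folding to min(m, 1−m); filtering is strict
(> 1%). Ranking sorts by score with lexicographic snp-id tie-breaks, then
thins for LD: a greedy pass in score order drops any SNP whose
pairwise-complete dosage r² with an already-kept SNP within 1 Mb on the
same chromosome exceeds 0.8 — keeping the best-scoring member of each
correlated set. Scoring-then-thinning is the default; `thin_first` flips
the order.

PCAIM scores follow the loading-weight scheme: per component,
|loading|/max|loading| (so each component's top contributor gets weight 1),
multiplied by the component's eigenvalue and summed over the TW-significant
components (p < 0.01 by default; the count and the weighting —
eigenvalue / variance-fraction / none — are configurable). Absolute
loadings and eigenvalue scaling make ranks invariant to component sign
flips and to overall spectrum rescaling. Because strongly differentiated
regions contribute many neighbouring SNPs to the same component, the final
panel collapses each 1 Mb physical cluster to its single best SNP.

Leave-one-population-out stability recomputes informativeness without each
population over the same filtered SNP universe (no re-thinning) and
Spearman-correlates against the full-panel scores.

## KNN ancestry assignment

Distances are Euclidean over raw dosages at the selected markers — no
standardization, which would silently re-weight markers. Missing cells are
imputed with reference per-marker means, so each query's assignment is
independent of the rest of the batch. The 5 nearest reference samples vote;
a label needs a strict majority (> half) of the polled neighbours, polled
at 5, then 4, then 3, else UNASSIGNED (strict majority is what makes the
fallback ladder meaningful; plurality would almost never fail at K = 5).
Exact distance ties break by reference sample order, deterministically.
Correctness credits the true population and any population whose pairwise
Fst with it is below 0.001; UNASSIGNED is never correct.

With few integer-valued markers, squared distances live on a coarse integer
grid and ties are common, so the reference ordering materially shapes the
neighbour lists; this is a real property of small-panel KNN on genotype
data, documented here because it caps how sharply near-identical
populations can be separated (see Limitations).

## Substructure

Within-population PCA drops SNPs monomorphic inside the population, then
runs the standard pipeline with Tracy–Widom tests. Subcluster detection
runs K-means (k-means++, 20 restarts, seeded) on the top-2 score axes for
k = 2…5 and keeps the k with the best mean silhouette, reporting "no
substructure" (k = 1) when that silhouette is below 0.45. The floor was set
empirically: K-means on a single unstructured 2-D Gaussian cloud attains
silhouette ≈ 0.33–0.40, so a lower floor would detect substructure in pure
noise, while genuinely separated subclusters score above 0.5. Emigrant or
admixed cohorts are profiled by KNN assignment over all shared markers,
reporting the fraction of the cohort absorbed by each reference population.

## The synthetic cohort generator

The generator reproduces the statistical regime of a multi-country
European-origin GWAS cohort; its defaults are the package's study
conditions.

* **Hierarchical differentiation.** Populations belong to regions
  (Scandinavia; a central core CZ/DE/NL; France, Britain, Poland as their
  own regions; Iberia; Italy; Greece). Each region draws one
  Balding–Nichols deviation per SNP (Beta with Var = F_reg·p₀q₀); each
  population adds an independent diffuse deviation with constant
  per-population F. Pairwise Fst expectation between populations of
  different regions is (F_reg,i + F_reg,j + F_i + F_j)/2 plus the cline
  term; same-region pairs drop the region terms. Values are calibrated so
  pairwise Fst spans ~0–0.014 with an indistinct core (CZ/DE/NL and
  NIT/SIT below 0.001) and the drifted northeastern outlier FI topping
  every row — FI's excess differentiation is entirely diffuse
  (bottleneck-like drift) and FI shares its region with NO and SE.
* **Locus heterogeneity.** Region deviations are scaled by a shared
  two-component per-SNP multiplier: an Exp(1) bulk plus a rare (0.5%)
  strongly scaled (130× Exp(1)) outlier class, rescaled so the multiplier's
  mean is exactly 1 — genome-average Fst is untouched while a minority of
  loci reach selection-scale frequency differences. The synthetic genome
  (12 000 SNPs by default) is ~50× smaller than the genotyping chip it
  emulates; the outlier class preserves the *absolute* strength of the
  strongest ancestry-informative loci rather than their relative share of
  a real genome, because small-panel assignment power depends on absolute
  per-locus differences.
* **Clines.** Each cline axis (default: a dominant NNW/SSE axis at −11°
  bearing, 0.012 frequency shift per 1000 km, plus a weaker orthogonal one)
  applies a shift strength·projection·g per SNP, where g is a sparse
  heavy-tailed susceptibility: 3% of SNPs are clinal with Exponential
  weights scaled so E[g²] = 2 regardless of sparsity. The genome-average
  cline contribution to pairwise Fst, (strength·d/1000)²·E[g²]/(2E[p₀q₀]),
  is therefore independent of how the signal is spread, while the top
  clinal loci approach fixation differences across the map — the analogue
  of the classic selected clines (lactase, pigmentation loci).
* **Genotypes, LD, missingness.** Dosages are two Bernoulli haplotypes per
  sample. Optional LD blocks copy the block's first SNP with per-haplotype
  flips at rate f, giving first-vs-member r² = (1−2f)² at frequency 0.5
  (attenuated away from 0.5). Missing calls are inserted uniformly
  (default 0.2%, post-QC scale). All randomness flows from a single seed
  through named substreams, so identical configs are bit-identical.
* **Study design.** Cohort sizes default to the emulated study's
  (39–475 per population, 2 362 total); `make_study_design` draws the
  harmonized 70-per-population reference, excludes undersized populations,
  sends populations with >10 leftovers to the test set, and isolates
  held-out populations (default SE, the "new population" probe).
  Emigrant/admixed cohorts are frequency mixtures: discrete (each sample
  wholly from one source) or per-sample admixed (w ~ Uniform, an extension
  beyond anything the emulated study specifies).

### What the generator does not emulate

Real LD decay (blocks are rectangular), within-population relatedness and
family structure, genotyping batch effects, and — most consequentially —
the full marker count of a genome-wide chip. Two documented consequences:
(1) PCA on 840 reference samples × 12 000 SNPs resolves only the strongest
3–6 axes (clines + the outlier population's drift axis); per-region
contrasts of magnitude n·F ≈ 0.05–0.1 sit far below the random-matrix
detectability threshold ≈ 2√(n_samples/n_snps), so PCAIM panels cannot
encode contrasts the informativeness ranking does carry. At the emulated
chip's 50× marker count that threshold drops ~7×, which is why the original
setting supports more significant components. (2) Sample-level separation
of populations at Fst ≈ 0.001 requires on the order of 10⁶ markers;
nearest-neighbour profiling over all 12 000 simulated markers therefore
spreads votes across the indistinct core and leaves many emigrant-cohort
samples unassigned, where the full chip would concentrate them. Passing
tests show the algorithms are correct and the regime qualitatively
reproduced; they do not show that 12 000 simulated SNPs carry the full
chip's resolving power.

## Problem sizes and runtime

Defaults were chosen so every analysis runs on one CPU in seconds to
minutes: the full study (2 362 × 12 000) end-to-end in ≈ 0.5–3 min, the
acceptance script in ≈ 35 s, the complete test suite in ≈ 1.5 min.
Multi-seed validation tests use 5 seeds; permutation tests use 1000
permutations (99 for null-calibration sweeps).
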