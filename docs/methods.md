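# Methods

## The analysis the package implements

The pipeline searches for one *linked component triplet* across three
subjects × features matrices — resting-state fALFF maps, VBM gray-matter
volume maps, and candidate-SNP minor-allele dosages — in a case-control
cohort, then characterizes that triplet: group differences, association with
working-memory scores, replication in an independent cohort, and mediation
structure along the genotype → structure → function → cognition chain.

### Feature preparation

Imaging maps are vectorized through a shared binary brain mask (column order
= linear voxel index; the discovery mask is reused for any replication cohort
so feature spaces align). Each modality is scaled so the mean subject-level
sum of squares equals a common target (default 1) *within each site*, with a
single scalar per site block. Age (mean-centred), sex (0/1) and site (k−1
dummies) are then regressed out of every feature column by OLS. The fixed
order is normalize → regress; residuals are not re-scaled. The composition is
deterministic, and each step is idempotent on its own, but the composition is
not exactly idempotent: re-normalizing regression residuals applies per-site
scalars that break exact orthogonality to the globally-centred covariates at
the 1e-3 level. Re-running the composition on its own output therefore
changes values slightly; the pipeline never does this, and the tests pin the
per-step properties instead.

An option (`covariates=("site",)`) reproduces the variant in which only site
is removed from the SNP matrix; the default treats all three modalities the
same. Missing medication doses are never imputed during preparation;
medication enters later, in the statistics stage, on the dosed subset only.

### Genotype QC

Filters operate directly on the 0/1/2 dosage matrix, thresholds strict as
worded: subjects with missing rate > 3% or heterozygosity (share of dosage-1
calls) beyond 3 SD of the cohort mean; markers with missing rate > 5%, MAF
< 0.01 (exactly 0.01 is kept), Hardy–Weinberg chi-square p < 1e-5, or
case-control call-rate-difference chi-square p < 1e-5; then greedy keep-first
LD pruning at |r| > 0.5 (exactly 0.5 is kept) in sliding blocks of 50 SNPs
stepping by half a block. The HWE test is the 1-df Pearson chi-square against
p², 2pq, q² at the sample allele frequency; monomorphic SNPs return p = 1. An
exact test is deliberately not used: the chi-square form is deterministic,
matches the p-threshold formulation of the filter, and is what the exhaustive
small-count oracle in the tests verifies. Relatedness filtering is out of
scope (no statistic or threshold is defined for it here).

Note a structural property of SD-based trimming: removing the most extreme
subject shrinks the SD, so a second pass can in principle trim again. The
chain reaches a fixed point on ordinary data (verified in tests), but strict
idempotence is not a theorem.

### Whitening, model order, Infomax

Whitening is an uncentered SVD in subject space: `Xw = sqrt(p) V_kᵀ` has unit
sample covariance over the p feature-samples, and `dewhiten @ Xw` is exactly
the rank-k SVD approximation of X, which makes `A @ S` reconstruct that
approximation identically and makes pseudoinverse self-projection exact.

Model order comes from either (a) the classic eigenvalue MDL: argmin over k
of `−N(p−k)·ln(geo/arith mean of trailing eigenvalues) + ½k(2p−k+1)·ln N`,
with an `iid_correction` factor that deflates the effective sample count for
spatially smoothed data (default 1.0: the synthetic features are i.i.d., so
no correction is warranted; real smoothed maps should set it below 1); or
(b) a stability curve: for each candidate order, Infomax runs on random 80%
feature subsamples from fresh seeds, components are matched across run pairs
by absolute loading correlation (loadings live in the shared subject space),
and the order with the highest mean matched correlation wins. Pure
re-seeding without resampling is explicitly warned against: Infomax on
identical data converges to the same optimum from almost any start, so that
curve is flat near 1.

Infomax itself is the standard natural-gradient ascent on the logistic
entropy objective, `ΔW ∝ (I + (1−2Y)Uᵀ/B)W` over permuted sample blocks
(B = 32), bias `w0` updated alongside, learning rate (default 0.008)
multiplied by 0.96 whenever successive weight updates turn by more than 60°.
Convergence is `‖ΔW‖²/C < 1e-7` within 512 passes; divergence triggers a
halved-rate restart, capped at 5. Block size 32 with the 0.96 anneal was
chosen for robustness of component separation across seeds on the
sample-starved SNP modality (500 features, order 10). Indeterminacy is
resolved canonically: unit-variance source rows, sign fixed so each row's
skewness is ≥ 0; downstream, `align_signs` re-signs components so mean HC
loading ≥ mean SZ loading.

### Three-way coupling

The joint objective adds `lambda * sum of r²` over constrained component
pairs, where a pair is constrained when its loading correlation magnitude
exceeds 0.2, at most 2 pairs per modality pair, re-selected every outer
iteration. Squared Pearson correlation was chosen as the aggregation: it is
differentiable, symmetric, sign-free, bounded in [0, 3] for a triplet, and
reduces to the familiar two-way coupling per pair. The gradient w.r.t. W uses
the chain rule through `A = dewhiten(W⁻¹)` via `∂f/∂W = −W⁻ᵀ (Dᵀ G) W⁻ᵀ`
(verified against finite differences in the tests).

Two scheduling choices matter in practice and are both deliberate:

* **Burn-in.** Coupling activates only after every modality's weight change
  has fallen below 1e-4. Early in optimization the components are still
  mixtures, the planted link's correlation is smeared over several columns,
  and coupling those transient pairs permanently distorts components.
* **Joint annealing.** The coupling step is scaled by the modality's current
  learning-rate ratio, so the coupling quiets down together with the ICA
  updates and the alternation converges instead of orbiting. `lambda` is
  additionally annealed (×0.9) if any entropy term degrades by more than 1%
  from its running best.

With `lambda = 0` the code path produces bit-identical results to three
standalone Infomax runs given the same fanned-out seeds (tested). The
linked triplet is the exhaustive argmax of the aggregation over all
C₁·C₂·C₃ triplets, ties resolved to the lowest lexicographic index.

### Statistics

Pairwise loading correlations are Pearson with two-sided t-transform
p-values; the Bonferroni family is all C₁C₂ + C₁C₃ + C₂C₃ pairs. The
two-sample test defaults to Welch: on the demographic table this package
mirrors, Welch reproduces the printed age p (0.05) from the printed moments
where the pooled test does not; the 2×2 chi-square defaults to Pearson
without continuity correction for the analogous reason (replication-cohort
gender p = 0.96). Two entries in that table (discovery gender p = 0.39,
replication age p = 0.14) are not reproducible from the printed summaries by
any standard chi-square/t variant; they are not used as oracles. Partial
correlation residualizes both variables on the covariates and applies the
t-transform with df = n − k − 2; a variable fully explained by the covariates
returns r = 0, p = 1 rather than 0/0. Medication control regresses the
(centred) dose out of a loading on the dosed subset only, preserving that
subset's mean level so dosed and un-dosed patients remain comparable.
"10-fold stability" refits the fusion on each 90% fold complement, matches
the full-data triplet by source correlation (sign-aligned), and reports the
mean ± SD of the three pairwise correlations. Ancestry PCs are the left
singular vectors of the column-standardized, mean-imputed dosage matrix.

### Replication projection

Cohort 2 is prepared the same way (discovery mask/SNP list, own site
normalization, own covariate regression — adjustment happens before
projection, not after) and projected: `AA = Y S⁺`. Because the ICA residual
lies in the orthogonal complement of the source row space, self-projection
returns the fitted loadings exactly; the per-subject residual fraction is
reported as a diagnostic. Linkage statistics are then re-run unchanged,
optionally on a phenotype-defined subset, in which case group contrasts are
skipped when only one group remains.

### Mediation

Simple mediation X → M → Y with shared covariates: `a` from M ~ X + C, `b`
and `c′` from Y ~ X + M + C, `c` from Y ~ X + C; `c = c′ + a·b` holds exactly
by OLS algebra and is asserted per fit. The indirect effect is tested by a
plain percentile bootstrap (default 5000 resamples of subjects with
replacement; bias-correction deliberately omitted — the plain percentile
interval is what the resampling description specifies; its slight
under-coverage at moderate n is acceptable and is measured by the calibration
suite). Degenerate resamples (singular design, e.g. a lost site level) are
redrawn with a capped retry. Path-level significance (used for the "no direct
SNP → DB effect" reading of model B) is the parametric OLS t-test; only the
indirect effect is bootstrap-tested. The four-model suite (A: SNP→GM→fALFF;
B: SNP→fALFF→DB with GM as an extra covariate; C: SNP→GM→DB with fALFF; D:
GM→fALFF→DB) always controls age, sex, site dummies and diagnosis, and first
regresses medication out of the imaging loadings on the dosed subset.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, not a fixture: every
recovery, null and calibration claim is made against it.

* Sources are sparse super-Gaussian rows (Laplacian spikes on a 10:1 Gaussian
  background, support fraction 0.05), unit-norm, near-orthogonal by random
  supports.
* Loadings are standard normal; the triplet columns are drawn jointly
  Gaussian with the target 3×3 correlation via its Cholesky factor in the
  structural order SNP → GM → fALFF, which makes the generating chain
  coefficients exact and reportable. Defaults are the linked-triplet
  strengths such studies report: fALFF–GM 0.75, SNP–imaging 0.17.
* The triplet columns get an HC−SZ mean shift of d = (0.24, 0.21, 0.13) for
  (fALFF, GM, SNP) — effect sizes back-computed from group p-values of order
  4e-4 / 1.4e-3 / 0.04 at n ≈ 900 — and are scaled by 1.5 relative to the
  background components, emulating the empirical prominence of a reliably
  identifiable linked component (this is also what keeps the triplet inside
  the retained PCA subspace when the model order is under-specified by 3).
* Digit spans are generated through the chain: DB = 0.3·(fALFF loading) +
  noise by default (matching a fALFF–DB correlation of ~0.3), DF with weight
  0.19, then rounded into the task ranges 0–12 (DF) / 0–10 (DB). A
  `discretize_spans=False` switch keeps the continuous scores. For mediation
  pattern studies `mediation_chain_config` builds the targets from explicit
  path coefficients (defaults 0.3, 0.7, 0.15 direct, 0.5 to DB) so all four
  pathway models have decisive expected outcomes at n ≈ 900.
* Noise SD is 0.5 × signal RMS per modality (signal-to-noise power ratio 4,
  a moderate level typical of ICA simulation studies); sites get small
  per-feature intercepts (SD 0.1/√p) so covariate regression has real work;
  ages/sex/medication mimic the demographic table (ages ~N(28.7, 6.9) HC /
  N(27.8, 6.9) SZ; doses recorded for 54% of patients, ~N(411, 205)
  chlorpromazine-equivalent).
* Feature counts default to 2000/2000/500 and model orders to 8/6/10 —
  desk-scale stand-ins for the 78k/77k voxel and 4.5k SNP matrices and the
  13/10/25 orders of a full-scale study, sized so the whole pipeline runs in
  seconds.
* The dosage generator draws Hardy–Weinberg genotypes at MAFs uniform on a
  range, plants violators via an inbreeding coefficient (F = 0.5, excess
  homozygosity), and builds LD blocks by thresholding an equicorrelated
  latent Gaussian at the HWE genotype quantiles — the dosage-scale
  correlation is mildly attenuated relative to the latent one, which is fine
  for testing pruning but is not a calibrated LD model.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: spatial autocorrelation of imaging maps, realistic
LD decay along a chromosome, population stratification beyond a single axis,
site effects on variance (only means shift), and any nonlinearity in the
genotype–phenotype map.

## Problem sizes used by the tests and acceptance script

Recovery and replication checks run at n = 400 (discovery) and n = 166
(replication) with desk-scale features; the acceptance script's main fusion
runs the full synthetic study conditions (n = 905, 7 sites). Mediation
calibration uses 500 simulations at n = 200 with 1000 bootstrap resamples
(the CI-stability check verifies 1000 vs 5000 changes endpoints by less than
Monte-Carlo error); the pathway-pattern check uses 20 chain cohorts at
n = 905. Null-safety uses 20 zero-link cohorts at n = 300 with orders 4/4/4
plus a 200-draw permutation null. These sizes were chosen so each property is
measured with useful power while the whole suite stays interactive.

## Known limitations

* The coupling aggregation and constraint schedule are this package's own
  concrete choices for the loosely-specified "connection strength" term;
  equivalence with any particular reference toolbox is not claimed — recovery
  on planted ground truth is the correctness standard.
* MDL here is the classic i.i.d.-sample criterion with an optional effective
  sample-count deflation; on strongly smoothed real maps the uncorrected
  criterion over-estimates the order.
* The percentile bootstrap slightly under-covers at small n (the calibration
  suite bounds this at n = 200); BCa intervals are not implemented.
* LD pruning is greedy keep-first within sliding windows; it is deterministic
  and order-dependent, like the standard tool it mirrors, and can keep a pair
  correlated just under the threshold whose joint effect exceeds it.
* The fusion assumes subjects are aligned across modalities and complete;
  there is no missing-modality handling.
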