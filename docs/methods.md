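# Methods

## Problem and model

The package classifies post-radiotherapy glioma lesions as radiation
necrosis (label 1) or tumor recurrence (label 0) from four co-registered
MRI volumes (T1, T1C, T2, FLAIR) and a manual tumor mask. The classifier
is a logistic regression

y(x_i) = a_0 + Σ_{j=1..p} a_j x_ij,  p(y_i = 1 | x_i) = e^{y(x_i)} / (1 + e^{y(x_i)}),

on a small number p ≤ 10 of features chosen from tens of thousands of
candidates. The statistical machinery is built around the two problems
such data pose: extreme p ≫ n (up to ~65k features for ~51 patients) and
class imbalance (roughly 1:2).

Registration and segmentation are out of scope: inputs are assumed
co-registered with a binary mask. The pipeline consumes either NIfTI
studies or a ready patient × feature CSV.

## Feature extraction

**Nontexture (4).** Volume = voxel count × voxel volume (mm³). Size =
maximum pairwise distance between surface-voxel centers (computed on the
convex hull of the surface for speed; the diameter is attained there).
Solidity = mask voxels / convex-hull-image voxels (both counted on the
voxel grid, so a digitised convex body scores 1). Eccentricity =
√(1 − λ_min/λ_max) from the eigenvalues of the voxel-coordinate
covariance — 0 for a ball or cube, → 1 for a needle.

**Texture grid.** Per modality the bounding-box crop is processed per
grid point:

1. *Wavelet band-pass*: one-level 3D sym8 decomposition (periodized);
   the LLL and HHH sub-bands are multiplied by the ratio R, the six
   band-pass sub-bands by 1, then inverse-transformed. R = 1 is the
   identity; R < 1 emphasises band-pass structure; R > 1 the extremes.
2. *Isotropic resampling* to scale_mm (trilinear for intensity, nearest
   for the mask, pixel-area convention so physical extent is preserved).
3. *Quantization* of in-mask intensities to 1..n_gray: Equal
   (equal-probability/quantile bins from average ranks, so tied values
   share a level and the result is intensity-shift invariant), Uniform
   (equal width over [min, max]), or Lloyd (Lloyd–Max, i.e. 1D k-means
   with deterministic quantile initialisation).
4. *43 statistics*: 3 histogram moments (population variance, skewness,
   Pearson kurtosis) + 9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM.

Matrices are 3D and merged: GLCM counts in-mask voxel pairs over the 13
unique distance-1 directions into one symmetric matrix (normalised to
sum 1); GLRLM accumulates maximal collinear constant-level runs over the
same 13 directions; GLSZM uses 26-connected constant-level zones; NGTDM
follows the Amadasun–King definitions with 26-neighbourhoods, in-mask
neighbours only, and a small ε = 1e−6 stabiliser in Coarseness and
Strength. Gray level g in weighted statistics means the integer level
1..n_gray, not the original intensity.

The default grid is the full factorial R ∈ {1/2, 2/3, 1, 3/2, 2} ×
scale ∈ {1, 2, 3, 4} mm × {Equal, Uniform, Lloyd} × n_gray ∈
{8, 16, 32, 64}: 240 combinations × 43 statistics = 10,320 features per
modality, 41,284 handcrafted features per 4-modality study. Parameter
combinations that degenerate for a given lesion (e.g. the mask vanishes
at a coarse scale, or a constant ROI leaves a statistic undefined) have
the affected statistics imputed as 0 with a logged warning, keeping the
table rectangular. Nontexture features are computed once from the mask,
not per modality, since they depend only on lesion geometry.

**Deep features.** For each modality, the axial slice with the largest
in-mask area (ties → smallest index) and its two neighbours (clamped at
the box boundary) are cropped to the bounding box footprint, each
min-max scaled to [0, 1], bilinearly resized, and stacked as RGB. An
AlexNet-style backend consumes 227×227×3 and yields 4,096 features
(FC7); an Inception-v3-style backend consumes 299×299×3 and yields
2,048 (average pooling). Per-modality vectors are concatenated: 16,384 /
8,192 per study, 24,576 with both. Pretrained weights are not bundled:
the default backend is a deterministic stub (seeded random linear
projection of the 16×16×3 downsampled input), which is approximately
distance-preserving, so class-separable images give class-separable
features — enough to exercise fusion, reduction and selection. Real
networks plug in through the backend registry under the same dimension
contract. Zero-range channels become all-zero with a warning; the
intensity normalisation and non-padded crop are package choices (both
configurable in code) since nothing in the design pins them down.

## Univariate screen

Spearman's r_s (average ranks for ties, large-sample t approximation for
p) between each feature and the outcome, with a Bonferroni threshold
α/K, α = 0.05. K is an explicit argument: the reference analysis counts
comparisons at the statistic-family level (e.g. K = 176 for handcrafted
features = 4 nontexture + 43 statistics × 4 modalities), not the raw
table width, so the module never infers K on its own. Constant features
report r_s = 0, p = 1 with a warning.

## Gain-equation reduction

Stepwise forward reduction to 25 features. For candidate j with d
features already selected and D remaining:

Gain_j = γ·r̂_s(x_j, y)
 + δ_a·Σ_{c=1..d} w_c·(1 − MIC(x_c, x_j))‾
 + δ_b·(1/D)·Σ_{k=1..D} (1 − MIC(x_k, x_j))‾,
 w_c = 2(d − c + 1)/(d(d + 1)),

with defaults γ = 0.5, δ_a = 0.5, δ_b = 0 (the third term is
implemented and tested but inert by default). The triangular weights sum
to 1 for every d ≥ 1 and weight earlier selections more. Every
overbarred quantity is a mean over B imbalance-adjusted bootstrap
replicates (default B = 1,000; tests and the acceptance script scale
this down — the selected-set size is invariant to B). Design choices:

* r̂_s uses the **absolute** bootstrap-mean correlation. Strong negative
  correlations are as informative as positive ones for a screen, and a
  signed term would anti-select them; the signed variant is available
  (`signed_rs=True`).
* The same replicate set is shared across candidates **and** across
  iterations. Sharing within an iteration removes Monte-Carlo noise
  from the argmax; sharing across iterations additionally makes the
  pairwise (1 − MIC) means cacheable, so each feature pair is computed
  at most once per reduction.
* Ties in gain break lexicographically by feature name. The final list
  is ordered by descending gain at selection time.

**MIC.** MIC(X, Y) = max over k×l grids, k·l ≤ B(n), of normalised
mutual information I/log₂min(k, l), with B(n) = max(⌊n^0.6⌋, 4) — the
floor keeps the 2×2 grid admissible at small n. Implementation: the MINE
dynamic-programming approximation (equipartition one axis into l rows;
optimise the other axis's column cuts exactly by DP over the additive
per-column objective; take both orientations). For n ≤ 12 the search is
exhaustive over all cut placements on both axes, and tests compare this
against an independent brute-force enumeration. MIC(x, x) = 1 holds
exactly whenever some admissible grid equipartitions the sample (e.g.
the 3×3 grid at n = 51); bootstrap ties can keep it marginally below 1.

Reduced handcrafted (25) and deep (25) sets are fused by concatenation,
handcrafted first; name collisions are an error.

## Bootstrap modeling

**Imbalance-adjusted resampling.** Each of the N in-bag draws picks a
class with probability 1/2, then a member uniformly within the class.
This equalises expected class mass in every training replicate at the
cost of deviating from the plain-bootstrap 0.632/0.368 in-bag/OOB
arithmetic (N = 51: ≈ 32 distinct in-bag / ≈ 19 OOB); a `uniform` mode
provides the plain bootstrap, and tests verify that arithmetic there.
The tension between the two descriptions is inherent to the design and
left configurable rather than resolved. Replicates whose in-bag or OOB
set lacks a class are redrawn (up to 100 times); cohorts with fewer
than 2 per class fall back to the weakest usable contract (non-empty
OOB) with a warning.

**0.632+ AUC.** AUC is the Mann–Whitney statistic (ties count 1/2). Per
replicate, the model is refit in-bag and scored on its OOB set;
AUC′ = max(0.5, AUC_oob) and α_b = 0.632/(1 − 0.368·R_b) where the
relative overfitting rate R_b is 1 if AUC_oob < 0.5, interpolates
(AUC_app − AUC_oob)/(AUC_app − 0.5) when 0.5 ≤ AUC_oob < AUC_app, else
0 (clipped to [0, 1], with a guard when AUC_app = 0.5). The published
typesetting of the interpolation condition is ambiguous; this standard
reading is the default and a literal ratio reading
(1 < AUC_app/AUC_oob < 2) is available via `overfitting_rule="ratio"`.
The estimate is the mean over replicates of
(1 − α_b)·AUC(x, x) + α_b·AUC′, a convex combination bounded by its
components.

**Fitting.** Features are z-scored with whole-sample statistics before
any fit so bootstrap-averaged coefficients share a scale. Fits use IRLS
with an unpenalised intercept and ridge ε = 1e−4 on slopes: with in-bag
n ≈ 32 and p up to 10, separation is routine and the unpenalised MLE
diverges. Zero-variance in-bag columns are zeroed in the design, which
pins their coefficient at exactly 0 (equivalent to dropping the
column). Replicate fits run as one batched IRLS (stacked normal
equations), which is what makes B = 1,000-replicate selection
tractable. Tests check the single fit against scikit-learn's lbfgs
solver on the same objective.

**Selection and final model.** Greedy forward growth from every starter
in the reduced set, each step adding the feature maximising the 0.632+
AUC on a shared ensemble; per order 1..10 the best combination over
starters is retained (ties → earlier reduced-set rank), and the order
with the maximum averaged AUC wins (ties → smaller order). Greedy
growth from all starters provably matches exhaustive search at orders
≤ 2 and is checked against it on small instances in the tests. Final
coefficients â_j are element-wise means of the per-replicate in-bag
fits, including the intercept.

## Evaluation

Per replicate the model is refit in-bag ("training" role, scored on the
in-bag multiset) and scored OOB ("validation" role). Sensitivity (for
necrosis = positive), specificity and accuracy use threshold 0.5 on the
predicted probability — a package choice, configurable. Summaries give
mean, SD, SE and 1.96·SE (error-bar convention: SE at 95% confidence);
both SD and SE are emitted because conventions differ. Paired t-tests
compare replicate-aligned metric vectors of two models on the same
ensemble; identical vectors are flagged degenerate (p = 1), constant
nonzero differences report p = 0. The "validation" metrics describe the
per-replicate refits, not the final averaged-coefficient model — the
latter is reported separately as a convenience.

## Synthetic data: what it does and does not show

Phantoms: an ellipsoidal lesion centered in the grid; in-mask intensity
is white Gaussian noise smoothed to a class-specific correlation length,
affinely mapped to the class mean/SD; background is flat plus noise.
Defaults (grid 32³ at 1 mm, radius 8 mm, necrosis coarser/more disperse
than recurrence, strongest contrast on T1C/FLAIR) were chosen once as a
minimal texture-separable configuration. Feature tables: standard normal
columns, an equicorrelated block structure (ρ = 0.3, blocks of 10) among
noise features, and a mean shift of `effect_size` SDs (default 2) on the
informative columns; the default cohort is 16 positives / 35 negatives,
matching the reference design and configurable.

These generators validate the *machinery*: determinism, feature-count
contracts, oracle agreement of every texture statistic, selection-bias
control (null calibration), and parameter recovery under a known signal.
They do not emulate scanner physics, bias fields, registration error,
cystic/edematous lesion morphology, or the heavy-tailed, highly
correlated feature distributions of real radiomics tables — so passing
tests demonstrate correctness of the algorithms, not clinical
performance. Cohort-level headline numbers from any real study are
out of reach without the original images.

## Numerical choices and problem sizes

* Ridge ε = 1e−4 (slopes only); IRLS capped at 60 iterations (40
  batched), linear predictors clipped at ±30 inside fitting.
* Lloyd–Max capped at 100 iterations, quantile-initialised, hence
  deterministic.
* Wavelet: sym8, one level, periodization mode (perfect reconstruction
  to ~1e−7 on the grids used).
* NGTDM ε = 1e−6.
* Degenerate statistics imputed 0, never dropped.
* Single master seed per run; per-stage seeds derived via
  `SeedSequence.spawn`, so any stage reproduces in isolation.
* Tests and the acceptance script run the bootstrap machinery at
  reduced sizes (B between 2 and 200, tables of 30–200 features,
  phantoms of 16³–24³) — chosen as the smallest sizes at which each
  property under test is informative; all defaults remain at the
  full-scale values (B = 1,000, 25-feature reduction, orders 1–10).

## Known limitations

* The MINE approximation equipartitions one axis; at very small n it can
  undershoot the exhaustive MIC (the implementation switches to the
  exact search for n ≤ 12).
* Greedy forward selection is not globally optimal beyond order 2;
  with strong independent signals it matches exhaustive search, which is
  the regime the tests pin down.
* The stub deep backend is a fixed random projection: it preserves
  geometry but has none of a pretrained CNN's semantics; conclusions
  about deep-feature *content* require a real backend.
* Imbalance-adjusted draws make the in-bag class mix binomial(N, 1/2),
  so replicate-to-replicate variance is slightly higher than stratified
  half-and-half sampling would give.
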