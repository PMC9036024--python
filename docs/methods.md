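# Methods

## Radiomics features

Each region of a co-registered integer parcellation yields exactly 47
features, computed on the region's voxels only:

* **First-order (14):** mean, median, minimum, maximum, range, variance,
  standard deviation, skewness, Pearson kurtosis, energy (Σx²), root mean
  square, mean absolute deviation, histogram entropy (bits), uniformity.
  Variance and SD are population (ddof = 0) moments. A constant region has
  variance, range, and entropy 0; skewness and kurtosis fall back to 0.
* **GLCM (22)** and **GLRLM (11):** standard IBSI-style definitions on
  matrices built from discretized intensities. Discretization uses a
  fixed bin count (default 32) over the region's own min–max range, so
  texture features are invariant to global intensity shifts. The GLCM is
  symmetric and normalized to a joint probability mass; degenerate cases
  are defined (correlation = 1 on a constant region; all features 0 when
  no voxel pair exists at an offset). Texture matrices are computed per
  direction over the 13 unique distance-1 3D neighbours and features are
  averaged over directions.

The exact feature list is a package constant (`CANONICAL_FEATURES`) so an
alternative 47-feature inventory can be swapped in without touching the
extraction machinery. Run-length matrices are computed by a vectorized
fixed-point recursion on the run-length field; the test suite checks both
texture matrix types and all 33 texture features against brute-force
pair/run enumeration oracles to 1e-10 relative on small regions.

## Network construction

Per subject, each feature column is min–max normalized across regions
(constant columns are a hard error — silent NaNs would corrupt every
downstream edge). Feature redundancy (|Pearson r| > 0.9 between feature
columns, computed on region rows pooled over a reference cohort) is
removed greedily in canonical feature order; the retained list is fitted
once on the normal-control cohort and applied frozen to all subjects to
avoid leakage into classification and clustering. Edges are the Pearson
correlations between regions' retained-feature vectors; the full weighted
matrix is kept (no thresholding or binarization). Edge vectors use a
single canonical order: the row-major upper triangle, with edge ids
`"<i>_<j>"`, i < j.

Greedy order matters: scanning in canonical feature order keeps the first
member of each redundant cluster. Alternative orders would change the
retained set; the order is fixed and documented rather than configurable.

## Discrimination and consistent connections

Edgewise NC-vs-AD contrasts use the equal-variance pooled t-test
(two-sided), Bonferroni-adjusted by the edge count; Welch is available by
flag. Covariates are not regressed out of edges (only longitudinal
trajectories are covariate-adjusted). The classifier is a linear SVM
(C = 1, fixed and recorded) with stratified ten-fold cross-validation
seeded from the caller; AUC is computed from pooled out-of-fold decision
values, ACC/SEN/SPE at decision threshold 0, and reported weights are
refit on the full data. A single stratified train/test split is available
as an alternative scheme. "Consistent" connections are the intersection
of {adjusted p < α} with {|weight| in the top fraction (default 5%)};
an empty intersection is a hard error, since the subtyping stage has no
feature space without it.

## Subtyping

Edge weights in [−1, 1] are mapped to [0, 1] by the invertible,
order-preserving affine map (x+1)/2 (rather than absolute value or
clipping, which lose information). Rank-2 NMF minimizes the Frobenius
reconstruction error with multiplicative updates: H is initialized
randomly per restart, W deterministically from the data given H
(W = XHᵀ/‖H‖²), which makes the factorization exactly equivariant under
subject permutation. Default 20 restarts; convergence when the relative
error change drops below 1e-6, capped at 500 iterations; the
per-iteration error trace is returned and asserted non-increasing.
Subjects take the label of their larger coefficient; the A-like
probability is the coefficient ratio. Components are named by the
Euclidean distance of their coefficient-weighted centroid to the AD and
NC group mean profiles in the same consistent-edge space. Reproducibility
across parcellations/runs is quantified by a symmetrized overlap AUC
(each run's A-like probability scored against the other run's hard
labels) and the Pearson correlation of the A-like probabilities.

## Characterization

Conversion is the first follow-up visit with an AD diagnosis; time is
months from baseline, administratively censored at the last visit.
Windowed conversion proportions count converters within the window over
subjects at risk (converted within the window, or followed at least to
it); subjects censored earlier are excluded from the denominator, which
is why at-risk counts can be smaller than group sizes. Kaplan–Meier
estimation uses the product-limit estimator (via lifelines, verified
against an explicit risk-set oracle); the log-rank test is implemented
directly from risk-set sums and cross-checked against lifelines.
Permutation p-values always use the +1 correction, (1+k)/(n+1), and never
return 0. Longitudinal trajectories residualize each measure against age
and sex with a linear fit estimated on baseline records of all subjects,
then average residuals per group per annual visit bin (months/12,
rounded).

CSF categories use Aβ+ iff Aβ < 980 pg/mL and Tau+ iff Tau > 245 pg/mL,
yielding Aβ+&Tau+, mixed, and Aβ−&Tau−. The chi-square test of category
proportions is Pearson's, without continuity correction.

## Imaging transcriptomics

Gene columns are z-scored across regions; the t-map is centered. The
first PLS component's gene weights are the classical single-response
solution w ∝ Xᵀy (unit norm); region scores are Xw. Although the t-map
plays the role of the independent variable, the component lives in gene
space — the standard imaging-transcriptomics construction. The component
sign is fixed so that its correlation with the t-map is nonnegative;
weights and scores flip together. Variance explained is the share of the
standardized expression (X-block) variance captured by the rank-1
reconstruction, which is 1 in the single-gene case. Significance uses
uniform permutation of the t-map's region labels; spatial-autocorrelation
preserving nulls are not implemented, a known limitation that makes the
permutation p anti-conservative on smooth real maps (irrelevant for the
exchangeable synthetic regions). Named-gene correlations are Bonferroni
corrected over the queried list only. The ranked gene export orders by
descending weight with lexicographic tie-breaks, one symbol per line.

## Synthetic data

The generator emulates the study's statistical structure, not its
anatomy:

* A regions × features template is drawn N(0, 1). The **AD pattern**
  subtracts `effect_size` times a fixed per-feature magnitude vector
  (uniform on [0.5, 1.5]) from a fixed random 20% of regions. The
  heterogeneity across features is essential: it changes the *shape* of
  affected regions' profiles, hence their correlations — a constant shift
  would leave every edge untouched. Per-subject measurement noise is iid
  Gaussian (`noise_sd`, default 0.5).
* NC subjects carry the template, AD subjects the shifted pattern, and
  each MCI subject carries the AD pattern with probability
  `frac_mci_adlike` (default 0.67, the approximate A-CI share of a
  typical MCI cohort).
* Clinical measures (MMSE, ADAS-cog, AVLT, PHS, FDG, CSF Aβ/Tau/P-tau)
  are drawn around NC/AD anchor means patterned on published aging-cohort
  values, with MCI interpolated toward the AD anchor by 0.65 (AD-like) or
  0.25 (NC-like).
* Follow-up is annual (`n_visits` = 6 years). Conversion times are
  exponential with baseline hazard set so that ~22% of NC-like MCI
  convert within three years, and an AD-like hazard ratio of 3.9 (which
  puts AD-like three-year conversion near 62%). Events are observed at
  the first annual visit after the latent conversion time, censored at
  the last visit. Cognitive decline rates at follow-up depend on the
  latent pattern; age and sex have no planted effect on the measures, so
  covariate adjustment is exercised as a no-op plus a dedicated test with
  a planted age slope.
* Labeled volumes partition a compact grid into raster-contiguous,
  near-equal regions (each ≥ 27 voxels enforced); regional intensities
  mix a region mean, a lattice-parity texture amplitude, and voxel noise
  so texture features genuinely differ between regions.
* Expression matrices plant `n_signal` gene columns as positive multiples
  of a supplied regional statistic plus noise; the rest are pure noise.
  Signal identities and slopes go to a separate truth table.

Latent truth (pattern labels, true conversion times) is never written
into the phenotype columns the pipeline consumes. What passing tests on
this generator do **not** show: robustness to scanner/site effects,
registration error, missing data, non-exponential hazards, or spatially
autocorrelated expression — none of which are modeled.

## Problem sizes and determinism

The test suite and examples run the pipeline at 50 NC / 60 MCI / 50 AD
subjects with 60 regions — large enough for the planted structure to be
recovered with margin (label agreement ≥ 0.9, log-rank p ≪ 0.01) while
keeping a full end-to-end run under a second. Null-calibration suites use
200 replicate cohorts at 50 subjects per group with 20 regions. All
stochastic components (cohort generation, fold assignment, NMF restarts,
permutations) are driven by explicit integer seeds, and identical
spec + seed yields byte-identical synthetic data.
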