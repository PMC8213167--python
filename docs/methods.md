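# Methods

## Scope and model

`autocyto` re-implements the algorithmic core of an autonomous cytometry
analysis framework: a document data model (project → experiment → subject →
sample → populations) with pluggable persistence, FCS ingestion with
spillover compensation applied at the point of entry, reversible intensity
transforms applied on demand (data are stored on a linear scale), autonomous
gates with hyperparameter search and landmark registration, batch-effect
diagnostics, per-sample clustering with centroid meta-clustering, a
supervised cell-classifier contract, and a population feature-space /
feature-selection cascade. Everything is testable against synthetic cohorts
with per-event ground truth; no external data or services are required.

## Compensation and transforms

Compensation solves `X_comp = X @ S⁻¹` over the spillover channels, with `S`
unit-diagonal and checked for conditioning (condition number ≤ 1e12);
non-fluorescence channels pass through. Spillover comes from `$SPILLOVER` /
`SPILL` / `$COMP` keywords or a labelled CSV.

Transforms are strictly monotone with exact inverses:

| kind | params (defaults) | notes |
|---|---|---|
| linear | a=1, b=0 | identity by default |
| log | base=10, offset=0 | defined for x+offset>0 |
| arcsinh | cofactor b=150 | mass-cytometry standard |
| biexponential | T=262144, w=0.5, m=4.5, a=0 | logicle family |

The biexponential is the Parks–Roederer–Moore logicle: the scale→data map
`s(y) = p·e^{by} − q·e^{−dy} + f` is closed-form (with `d` solved by Brent's
method from the linearisation-width constraint), and data→scale is a
safeguarded Newton iteration seeded from a dense grid; round-trips are
accurate to ~1e-15 relative, far inside the 1e-8 contract. The
parameterisation is exposed because the field uses several "biexponential"
conventions; these defaults match common instrument-software scales.
`zscale` standardises with population SD (ddof=0, matching common scaler
semantics) and refuses zero-variance columns by name.

## Autonomous gates

**Threshold gates.** Per dimension a Gaussian KDE (Silverman's rule by
default, bandwidth exposed) is evaluated on a 1000-point grid spanning the
0.1–99.9 percentile range. With ≥ 2 density peaks above `min_peak_threshold`
(default 5% of the maximum; exposed and searchable — rare populations can
need 1%), the threshold is the density minimum between the two tallest
peaks; otherwise the `q_fallback` quantile (default 0.95). 2-D gates
threshold each dimension independently (quadrant gates). Children are the
sign partition of the parent — exactly, by construction.

**Ellipse gates.** A Gaussian mixture (scikit-learn, seeded) with `n_components`
searchable; each child is the event set within the chi-square(2) quantile of
squared Mahalanobis distance at `conf_level` around a component mean.
Components are named at definition time by nearest component mean to a
stated prototype point.

**Matching.** A gate is defined on example data; each example population is
stored as a reference with an MFI vector (median per dimension, transformed
space) and, when non-degenerate, a convex hull. On application the algorithm
is refitted and candidates matched back: threshold gates by minimum
Euclidean MFI distance, geometric gates by minimum symmetric Hausdorff
distance between hull vertex sets (vertices, not member events: cheaper and
scale-free). Assignment is greedy-injective in ascending distance with
first-encountered tie-breaks.

**Hyperparameter search.** The cartesian product of the grid (cap 512) is
refitted exhaustively. For threshold gates the grid point with the most
matched references, then the smallest total matching distance, wins as a
whole — the committed children therefore always form one sign partition of
the parent. (Selecting each reference's winner from a different grid point
would break the partition and occasionally lets a mis-fitted quadrant
capture a rare population's reference; a single coherent partition per gate
removes both problems.) Ellipse gates select per-reference winners across
grid points, since their children may legitimately overlap.

## Landmark registration

Landmarks are KDE local maxima above a prominence floor (5% of maximum
density); at least one (the global maximum) is always returned. Reference
and target landmarks are paired: with equal counts, by rank order (a
monotone warp preserves order, so rank pairing is the correspondence the
warp itself implies); with unequal counts, by K-means grouping of the pooled
positions (k = larger landmark count), each mixed cluster contributing its
closest cross-source pair. The warp is a monotone cubic (PCHIP)
interpolation through the knots, continued with identity slope beyond the
outermost knots, so it is strictly increasing on ℝ and maps each paired
target landmark exactly onto its reference landmark. Gates store the example
data's landmarks per dimension and can re-register each new sample locally
at application time; a registration failure leaves the data unchanged and
logs a warning.

## Batch diagnostics and correction

The reference sample is the one minimising the mean Frobenius (entrywise
Euclidean) distance between channel covariance matrices — invariant to any
common orthogonal rotation; ties break by sample-id order.

LISI uses hard k-nearest-neighbour batch proportions (default k=90, self
excluded): `LISI = 1 / Σ_b p_b²`, bounded in `[1, B]`. The hard-kNN variant
is brute-force verifiable (the suite checks exact agreement with a full
pairwise-distance implementation); the neighbourhood size is exposed since
plot-level choices vary.

`correct_batches` is a contract around a plugin
`(matrix, batch_labels, params) → matrix`: biexponential transform (or any
configured `TransformSpec`), optional uniform per-sample down-sampling with
a stored seed, pooling with origin labels, per-dimension unit-variance
scaling, then the plugin. Default plugin parameters are σ=0.2 and
max_iter=5. Shipped plugins: `identity` and `mean_center` (per-batch mean
centring — removes pure location batch shifts without touching within-batch
covariance); a full corrector such as Harmony registers through the same
signature.

## Clustering and classification

Clustering plugins are callables `(matrix, params, seed) → integer labels`
(−1 = noise). Centroids are per-dimension medians (robust; configurable to
means). Meta-clustering min-max scales the stacked centroids per dimension
across samples, clusters them with a plugin, and reports per-(sample,
cluster) meta-ids, median meta-centroids, and per-sample proportions. Both
cluster and meta-cluster results commit as Population documents, exactly
like gates, so feature extraction is source-agnostic. The classifier
contract accepts any fit/predict model, requires non-overlapping training
labels, and reports stratified 5-fold cross-validated weighted F1 plus a
confusion matrix.

## Feature selection

Features are per-subject population statistics (fraction of parent,
fraction of root, count), averaged across methods when a population was
derived by several (missing populations recorded as NaN and excluded from
complete-case models), joined with subject metadata covariates. The cascade:

- **Collinearity filter** — |Spearman ρ| ≥ threshold (default 0.9); the
  lower (min-max-scaled) variance member of the pair is dropped. Pairs are
  processed in descending |ρ| with lexicographic tie-breaks, so the result
  is invariant to column order.
- **Variance filter** — min-max-scaled variance below a floor (default
  0.02) drops the feature; a balanced binary feature (scaled variance 0.25)
  survives comfortably.
- **PCA** — on standardised complete cases; unit-norm loadings, explained
  variance ratios.
- **L1 path** — L1-penalised linear SVM (squared hinge, liblinear-style
  primal) or logistic regression over 30 log-spaced C values across 4
  decades, descending. Persistence = smallest C with |coef| > 1e-6; ranking
  by persistence, then max |coef|.
- **Decision tree (gini)** — depth-1 stumps are fitted by exhaustive split
  search with a deterministic tie-break: equal gini decrease resolves to
  the split with the larger standardised margin at the cutoff, then feature
  order. (A library tree breaks such ties by random feature permutation,
  which made the reported root split nondeterministic whenever two features
  both split perfectly.) Deeper trees delegate to scikit-learn.
- **Group comparison** — two-sided Mann-Whitney U (exact null when the
  smaller group has ≤ 8 subjects and no ties; tie-corrected normal
  approximation otherwise) with Holm step-down adjustment.

## Synthetic cohorts

The generator emulates a multi-sample cytometry cohort: per-population
multivariate Gaussians in channel space, per-sample affine batch
perturbation (per-channel shift ~ N(0, τ²), scale ~ LogNormal(0, s²)),
spillover mixing (so compensation is exercised end-to-end), per-sample
Dirichlet dispersion of population frequencies (between-subject biological
variation — without it, compositional renormalisation makes every fraction
a near-noiseless proxy of the case label, which no real cohort exhibits),
and a case/control frequency multiplier on one population. All randomness
derives from a single seed via spawned generators; ground-truth per-event
labels and realised frequencies accompany every sample.

The flagship cohort fixes the default study conditions: 14 samples, 4
cases, 6 channels, 6000 events per sample, 5 populations — two T-cell-like
(34%/31%), a monocyte-like (30%), a scarce neutrophil-like (4%) and a rare
MAIT-like population (1%) — with τ=0.3, s=0.08, Dirichlet concentration 60
(≈20% CV on major fractions), nearest-neighbour spillover of 2–6%, and a
12× neutrophil elevation in cases. The geometry mirrors acute bacterial
infection of the peritoneal cavity, where neutrophils are scarce in stable
patients and dominate the infiltrate during acute episodes, and lets a
three-gate threshold strategy (lineage split, T-subset split, myeloid
quadrants) isolate every population.

What the generator does **not** emulate: nonlinear (non-affine) batch
distortions, acquisition-time drift, margin/doublet/debris events,
non-Gaussian population shapes, and panel-to-panel differences. Passing
tests therefore demonstrate correctness of the algorithms under controlled
drift and compositional noise — not robustness to every artefact of real
instruments; acquisition QC is expected to happen upstream.

## Numerical and design choices

- KDE grid: 1000 points over the 0.1–99.9 percentile range; prominence and
  peak floors as fractions of maximum density.
- All stochastic fits (GMM, K-means, L1 models) take explicit seeds;
  default 42. Pipeline steps derive seeds from the global seed and the step
  name (CRC32 mix, kept below 2³¹).
- Tie-breaks are first-encountered (lowest grid index, lowest candidate
  index, lexicographic names) and documented where they bind.
- Persistence backends: in-memory and JSON files with CSV event-matrix
  sidecars; round-trip is exact (text floats at %.17g). A document-database
  backend can implement the same four-method contract.
- Deleting a population deletes its descendants (tree invariant
  preservation).
- FileGroups are experiment-local; registering one FCS file in two
  experiments creates two independent FileGroups.
- Events containing non-finite values after ingestion are dropped and
  counted, not imputed.

## Problem sizes in the suite

The default test suite and the acceptance script run the flagship cohort at
its native size (14 × 6000 events), 20-seed repetitions for the
meta-clustering and cascade properties, 50 perturbation pairs for the
registration property, and 500-event instances for brute-force oracle
comparisons; the whole suite completes in well under a minute on one core.

## Known limitations

- Quadrant (2-D) thresholds are per-dimension; a genuinely diagonal
  boundary needs an ellipse/GMM gate.
- Landmark registration warps each gate dimension independently; joint 2-D
  warping is not attempted.
- Greedy injective matching is optimal only when the assignment problem is
  near-diagonal (well-separated populations); a Hungarian assignment could
  replace it behind the same interface.
- The collinearity filter drops one member per correlated pair without
  considering higher-order redundancy (no VIF).
- The L1 "persistence" ranking assumes standardised features; it is not
  meaningful on raw, scale-incommensurate columns.
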