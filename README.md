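# autocyto

Autonomous analysis of flow and mass cytometry data: replace hand-drawn
gates with fitted density and mixture-model algorithms, quantify and correct
batch effect, match cell populations across samples by meta-clustering, and
distil per-subject population statistics into the few features that predict
a clinical endpoint.

It is written for immunologists and cytometry bioinformaticians who analyse
multi-sample cohorts (e.g. patients accrued over months on a drifting
instrument) and want a scriptable, fully seeded pipeline instead of manual
FlowJo-style analysis — and for method developers, since every stage
(gating algorithm, batch corrector, clusterer, classifier) is a plugin
behind a small contract.

## What it computes

- **Compensation at entry** — observed intensities `X` are corrected with
  the spillover matrix `S` as `X·S⁻¹`; data stay on a linear scale with
  biexponential (logicle), arcsinh and log transforms applied on demand.
- **Autonomous gates** — 1-D/2-D density threshold gates (KDE valley
  between the two tallest peaks, quantile fallback) and Gaussian-mixture
  ellipse gates (chi-square Mahalanobis cut at a confidence level). A gate
  defined on example data stores its populations as references (MFI vector
  or convex hull); on new samples the algorithm is refitted — optionally
  over an exhaustive hyperparameter grid and after landmark registration —
  and candidates are matched back by minimum Euclidean MFI distance or
  minimum Hausdorff hull distance.
- **Landmark registration** — per-channel density peaks of a target sample
  are warped onto a reference by monotone cubic interpolation, aligning
  batch-shifted distributions before a gate is applied.
- **Batch diagnostics** — reference-sample selection by minimum mean
  Frobenius distance between covariance matrices, and LISI (local inverse
  Simpson's index over k nearest neighbours): ≈1 when batches segregate,
  ≈B when B batches mix. Global correction is a plugin contract
  (biexponential transform + unit-variance scaling + pooling, σ=0.2,
  5 iterations by default).
- **Meta-clustering** — each sample is clustered independently; cluster
  centroids are min-max scaled and clustered again to match populations
  across samples without pooling events.
- **Feature selection** — a subjects × population-statistics table run
  through collinearity (Spearman) and variance filters, PCA, an
  L1-regularised coefficient path over a descending C grid, a shallow gini
  decision tree, and Mann-Whitney U tests with Holm correction.
- **Synthetic cohorts** — a first-class generator (Gaussian mixtures,
  affine batch drift, spillover, Dirichlet frequency dispersion,
  case/control effects, FCS 3.1 writer) provides ground truth for every
  stage.

## Worked example

`examples/02_autonomous_gating.py` generates the flagship synthetic cohort —
14 samples (4 "case"), 6 channels, 5 populations including a rare 1% subset,
with per-sample batch drift and spillover — defines a three-gate threshold
strategy on the first sample, and applies it to the rest with hyperparameter
search and landmark registration:

```
sample_id population  true_fraction  recovered_fraction
sample_00  tcell_cd4       0.194333            0.194333
sample_00  tcell_cd8       0.183667            0.183333
sample_00   monocyte       0.269333            0.269000
sample_00 neutrophil       0.352667            0.353000
sample_00  mait_like       0.000000            0.000333
...
Pearson r (true vs recovered fractions, 70 sample-population pairs): 1.0000
worst absolute fraction error: 0.77 percentage points
```

Each row compares a population's ground-truth fraction of a sample with the
fraction recovered by the refitted gates; `r ≈ 1` across all 70
sample-population pairs means the autonomous strategy tracked every
batch-shifted sample, including the rare subset — the synthetic analogue of
agreeing with expert manual gates. The other examples each demonstrate one
capability (ingestion/compensation, registration, LISI diagnostics,
meta-clustering, feature selection) and print what their numbers mean.

A thin CLI wraps the same functions
(`cyto synth | ingest | batch-report | correct | cluster | features |
pipeline`); `cyto pipeline --seed 42 --out run/` executes the whole workflow
on the flagship cohort and writes the recovery table, feature CSV and a
machine-readable run log.

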