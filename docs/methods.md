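# Methods

## Problem and pipeline

`sdconnectome` implements a connectome-based biomarker pipeline for
subclinical depression (SD): given resting-state ROI time series for a
cohort of SD subjects and healthy controls (HC), it asks which anatomical
regions' functional connections can classify group membership, and which
subregions show altered weighted connectivity. The pipeline has five
computational stages:

1. **Network construction.** For each subject, the Pearson correlation
   r_ij between every pair of subregion time courses is computed,
   variance-stabilised with Fisher's r-to-z (z = arctanh r), and converted
   to a non-negative edge weight W_ij = |z_ij| / max|z| in [0, 1]. The sign
   of a resting-state correlation is controversial to interpret, so the
   absolute value is used. The diagonal is zero: self-connections carry no
   information. The weighted node degree is k_i = Σ_j W_ij.
2. **Edge screening.** Each of the N(N−1)/2 edges gets a two-sample
   t-test (pooled variance; Welch optional) on its weight between groups.
   Benjamini–Hochberg adjusted q-values are computed and reported, but the
   default selection mask is *uncorrected* p < 0.05: the screen is a feature
   selector feeding a classifier, not a final inference, and strict FDR
   control at this stage empties the candidate set long before the
   classifier can use it. `mask_criterion="q"` switches to adjusted values.
3. **Leakage control.** Feature selection inside cross-validation must not
   see the test subject. A *mask family* therefore holds one mask per
   leave-one-out fold, recomputed with that fold's subject excluded, plus a
   full-cohort mask used only for descriptive group analyses.
4. **Classification.** Three families of connection-feature sets are
   evaluated with an RBF-kernel SVM
   (K(x_i, x_j) = exp(−γ‖x_i−x_j‖²)) under leave-one-out
   cross-validation: one model per bilateral anatomical region (edges
   incident to the region's subregions), one per sliding window of
   consecutive subregions (row-by-row over the adjacency matrix,
   n − w + 1 windows), and a baseline of random subregion sets. (C, γ)
   are grid-searched by stratified inner cross-validation on the training
   subjects of each fold; ties resolve to the smallest C, then smallest γ
   (the smoothest model), making the whole evaluation deterministic given a
   seed. Per-fold decision values are pooled into a single ROC curve; AUC
   equals the tie-aware Mann–Whitney probability. SD is the positive class.
5. **Profiling.** On the full-cohort mask: per-region connection counts,
   mean p-values, and partner-region attribution; Pearson checks of whether
   model accuracy merely tracks connection count or p-value; a random
   connection-subsampling experiment (accuracy after reducing a region's
   connections to a target count); and per-subregion two-sample tests on
   weighted degree at α = 0.01.

## Feature-set scopes

Anatomical and window models use `scope="incident"`: every masked edge with
at least one endpoint in the node set. The random baseline uses
`scope="within"` (edges with both endpoints inside the set): a random
scatter of subregions has no meaningful incident neighbourhood, and with
incident scope a random set inevitably touches the same edges as the
informative regions, which would make the baseline vacuous. Both scopes are
available on every family via `FeatureSpec.scope`.

## Parcellation

Networks are defined on a 246-subregion bilateral parcellation: 24 merged
regions × 2 hemispheres (48 hemispheric regions), with per-hemisphere
subregion counts summing to 123 and the thalamus owning 8 subregions per
hemisphere (16 total). The table is generated programmatically
(`brainnetome_parcellation()`); it carries subregion labels, hemispheric and
merged region columns, and flags — the right posterior parietal thalamus
subregion (PPtha_R) is flagged `contains_LHb`, marking the lateral habenula's
location as metadata. Voxel-level atlas deployment is out of scope; the
pipeline consumes already-extracted ROI time series. Arbitrary-size toy
parcellations (`uniform_parcellation`) support testing.

## Synthetic cohort generator

Real fMRI for this design is not redistributable, so a generator produces
cohorts with the structure the pipeline assumes. Per subject, T i.i.d.
samples are drawn from a zero-mean multivariate normal with correlation
matrix C_g(s):

- **Base structure.** Block-structured base correlation: 0.35 within a
  merged region, 0.20 between regions (defaults). Temporal autocorrelation
  is deliberately not modelled — the pipeline only consumes sample
  correlations.
- **Planted effects.** Edges incident to the designated regions are shifted
  by ±effect_size/2: lowered in SD, raised in HC by default (`sd_weakened`),
  matching the dominant empirical direction of reduced coupling in SD.
- **Anchor pair.** One non-planted pair of nodes carries a group-invariant
  correlation of 0.8. Because each subject's weights are normalised by their
  own maximum |z|, the maximum must not itself differ by group; the anchor
  pins it. Without this, the normalisation divisor carries the planted
  effect and every null edge becomes spuriously group-different —
  verified by the type-I calibration tests.
- **Subject heterogeneity.** A symmetric N(0, 0.05²) perturbation of each
  subject's correlation matrix (then PSD-repaired) makes edge weights vary
  within group, which the edge-wise t-test requires. The within-group
  variance of real edge weights is unknown; 0.05 is a free parameter chosen
  to give realistic edge-level effect sizes at the default design.
- **PSD repair.** Eigenvalues clipped to 1e−8, diagonal renormalised to 1.
  If the repaired matrix deviates from the target by more than 0.05 on any
  entry, generation fails naming the offending edges rather than silently
  sampling from a different population.
- **Demographics.** Ages ~N(19.8, 1.2²) clipped to 19–25, education
  ~N(13.1, 0.6²), sex rates matched to the reference design, BDI-II > 13 in
  the SD group (gamma-tailed) and ≤ 13 in HC — group-matched in
  expectation, so demographic tests (t for age/education, Pearson chi-square
  without continuity correction for sex) are null.

Defaults reproduce the reference design: 34 SD + 40 HC subjects, 246
subregions, 180 retained timepoints.

**What passing tests show.** The generator emulates second-order structure
(group-differential correlations) only. It does not emulate temporal
autocorrelation, physiological noise, motion artifacts, site effects, or
the diffuse, weak effect landscape of real disorders — planted effects are
localized and, at the default effect size of 0.4, individually strong.
Passing power tests therefore demonstrate that the pipeline recovers the
structure it assumes, not that real SD is classifiable at any particular
accuracy.

## Numerical and design choices

- **Normalisation scope.** Per-subject maximum by default; a cohort-wide
  maximum (`normalization="cohort"`) preserves between-subject weight
  comparability. Within-subject edge ranking is identical under both.
- **Perfect correlations** are clipped at |r| = 1 − 1e−7 (z ≈ 8.4) with a
  warning; the affected edge keeps the maximal weight.
- **Degenerate edges** (zero variance in both groups) get t = 0, p = 1 with
  a warning instead of NaN.
- **Empty feature sets.** A fold whose mask leaves a model no connections
  predicts the training majority class and logs the event; its decision
  value is the training SD fraction minus ½.
- **Inner CV.** 5-fold stratified by default, automatically reduced to the
  smallest class count; grid search uses a strict-improvement scan so
  duplicated scores keep the smallest (C, γ).
- **Nested vs global tuning.** Grid search runs inside every LOO fold by
  default (leakage-safe); `search="global"` tunes once on all data for
  comparison and is intentionally optimistic.
- **Subsampling experiment** draws edge subsets from the full-mask feature
  pool and intersects them with each fold's own mask; folds with fewer
  available edges than the target use what they have and log it.

## Problem sizes in the test suite and acceptance script

Simulation-backed checks run at reduced scale chosen to keep the
distributional questions intact: calibration cohorts of 30 subjects /
30–40 nodes, power cohorts of 80 subjects / 60 nodes at effect 0.4 with 180
timepoints, and the acceptance script's flagship run at the full reference
design (74 subjects, 246 nodes) with a thalamic planted effect. Test-scale
SVM grids span 2–3 values per hyperparameter; the full LIBSVM-style grids
(C = 2^−5…2^15, γ = 2^−15…2^3) remain the library defaults.

## Known limitations

- The LOOCV + nested-grid-search protocol is faithful but expensive; at
  atlas scale the 231 window models and 100 random models are an overnight
  batch rather than an interactive run.
- ROC curves pool uncalibrated per-fold decision values; with per-fold
  retuning the pooled AUC is a summary, not a strict probability estimate.
- The mask criterion (uncorrected p) and the within-scope random baseline
  are modelling choices exposed in config, not settled facts.
- Region-level inference is descriptive: no permutation or network-based
  statistic controls family-wise error across regions.
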