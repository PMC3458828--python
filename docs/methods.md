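# Methods

## Connectivity model

Probabilistic tractography seeds a fixed number of streamline samples per
voxel (`samples_per_voxel`, default 5000) in each of 90 AAL regions.
Writing *n<sub>i</sub>* for the voxel count of region *i* and
*m<sub>ij</sub>* for the number of streamlines from *i* that reach *j*,
the directed strength is the arrival fraction

    s_ij = m_ij / (samples_per_voxel · n_i) ∈ [0, 1].

Normalizing by seed-region size corrects for the large variation in AAL
region volumes, so that each connection contributes on a comparable scale.
Because seeding direction matters in probabilistic tracking, the edge
strength is the average of `s_ij` and `s_ji`; a floor (`threshold`,
default 0.01) then zeroes entries too weak to distinguish from
false-positive streamline spillover. The floor is applied **after**
symmetrization — the connectivity being thresholded is the edge value, not
its directed halves. Diagonals are ignored and forced to zero. Edges map
to feature positions in row-major upper-triangle order, fixed by
`EdgeIndex` (4005 features for 90 regions).

## Group statistics

Edge-wise group comparison uses the classical pooled-variance (Student)
two-sample t-test; Welch's form is available via `equal_var=False`.
Conventions for degenerate edges: zero variance in both groups with equal
means gives p = 1 (no evidence), with different means p = 0; the
significance matrix has a unit diagonal. Each subject's overall
connectivity is summarized as the mean of its nonzero upper-triangle
strengths (each edge counted once, zeros from thresholding excluded
per subject); the group contrast of these per-subject means is again a
two-sample t-test.

## Locally linear embedding

`fit_lle` follows the standard three-step construction: (1) k nearest
training neighbors per point by Euclidean distance, self excluded, ties
broken by ascending index; (2) reconstruction weights minimizing
`‖x_i − Σ_j w_ij x_j‖²` under `Σ_j w_ij = 1`, solved from the local Gram
matrix `C` of neighbor offsets with ridge `reg · trace(C)/k` added to the
diagonal (plain `reg` when the trace vanishes; `reg` defaults to 1e-3 and
is required whenever k exceeds the local intrinsic dimension); (3) the
embedding `Y` given by eigenvectors 2..d+1 of `M = (I−W)ᵀ(I−W)` in
ascending eigenvalue order, scaled by √n so the columns have unit
covariance. At cohort sizes (n ≤ a few hundred) a dense symmetric
eigensolver is used throughout. The construction assumes the neighbor
graph is connected; for disconnected graphs the zero eigenvalue is
degenerate and the embedding of separate components is arbitrary up to
rotation.

A held-out subject is projected by the reconstruction-weight out-of-sample
extension: solve the same constrained weight problem for the new point
against its k nearest training points and return the weighted combination
of their embedding rows. The source analysis design does not specify the
projection mechanism for the left-out subject; this standard extension is
a design choice of this package.

Features are z-scored per dimension with training-fold statistics before
the (distance-based) embedding; the toggle `standardize` disables it.

## Classification pipeline

Per leave-one-out fold: two-sample t-tests rank all edges on the N−1
training subjects; the `n_features` (default 50) smallest p-values are
kept, ties broken by larger |t| then smaller index, with an advisory
warning if any selected p exceeds `p_ceiling` (default 0.001 — selection
is never altered by the ceiling). The training subjects are embedded
(k = 23, d = 15; both clipped to what the fold's training size admits) and
a soft-margin SVM with Gaussian kernel `exp(−‖x−x'‖²/(2σ²))`, σ = 3, is
fit with patients as the positive class. The kernel normalization and the
cost parameter are not fully determined by the source design: the
conventional 2σ² denominator is the default (`kernel_dialect="sigma2"`
gives `exp(−r²/σ²)`), and C defaults to 1 and is logged. Decision scores
are signed distances; a score above zero predicts patient.

SS, SC and GR are exact ratios of the aggregated confusion counts,
reported as percentages and rounded to one decimal only at the reporting
layer. The ROC curve sweeps thresholds over the observed scores (tied
scores cross simultaneously) with trapezoidal AUC.

## Permutation test

Whole-cohort labels are shuffled and the **full** nested pipeline —
including in-fold feature selection — is re-run per permutation, which is
the conservative reading of label-permutation testing for
selection-inside-CV pipelines. The p-value uses the add-one estimator
`p = (#{null GR ≥ observed} + 1)/(B + 1)`, which cannot return zero. An
exhaustive mode enumerates all distinct label assignments for very small
cohorts.

A property worth knowing: under the null, the LOOCV generalization rate of
this pipeline is systematically **below** 50%. Every fold trains on an
imbalanced N−1 sample whose majority class is the opposite of the held-out
subject; with a σ = 3 RBF kernel the test point's kernel row is often
nearly uniform, pushing the decision toward the training majority, and
in-fold selection of the most separating features adds the classic
anti-learning bias. Measured on 20-subject null cohorts the pooled null GR
is ≈ 23%, not 50%. This does not invalidate the permutation test — the
permuted-label null distribution shares exactly the same bias, which is
why significance is assessed against it rather than against nominal
chance level.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of a two-group
tractography cohort:

- **Template.** A symmetric support of `density` (default 0.30) of the
  off-diagonal pairs, with log-normal edge strengths
  (`baseline_log_mean = ln 0.04`, `baseline_log_sd = 0.5`). The implanted
  ("affected") edges — default: a packaged set of 33 cortical-limbic and
  occipital-temporal region pairs — are always part of the support.
- **Subject noise.** Each subject multiplies every edge by an independent
  log-normal factor (`subject_log_sd = 0.6`, i.e. a per-edge coefficient
  of variation of ≈ 66%, in line with the large between-subject
  variability of normalized streamline counts) and by one shared
  log-normal global factor (`subject_global_log_sd = 0.1`). The global
  factor reproduces the realistic between-subject spread of whole-brain
  mean connectivity (SD ≈ 0.004–0.005 at the default scale), which
  independent edge noise alone would understate several-fold.
- **Group contrast.** Patients multiply the affected edges by
  `effect_multiplier`; a per-group global scale is then solved
  (Brent root-finding on the truncated-log-normal expectation, threshold
  truncation included) so the expected post-threshold mean nonzero
  strength equals the calibration targets, 0.0499 (patients) and 0.0412
  (controls). The patient group is therefore globally elevated by ≈ 16%
  on every edge on top of the implanted effect — matching the observation
  that group differences of this kind are broadly distributed rather than
  confined to a few edges. Setting `effect_multiplier = 1` makes the
  cohort exactly null: both groups are calibrated to the control target.
- **Effect size.** The default multiplier 3.3 places the implanted edges
  at a population Cohen's d ≈ 1.5 under the default noise
  (`implant_effect_size` computes this analytically from truncated
  log-normal moments).
- **Counts.** With `emit_counts`, directed streamline counts are drawn as
  `Binomial(samples_per_voxel · n_i, s)` around each subject's intended
  pre-threshold strengths, so rebuilding matrices through the connectome
  stage recovers them in expectation; the floor is applied at rebuild
  time, mirroring the real processing order.

What the generator does **not** emulate: spatially structured correlation
between edges (beyond the one global factor), distance- or
curvature-dependent tracking failure, partial-volume effects, and
site/motion artifacts. Passing tests on these cohorts therefore
demonstrate the correctness and calibration of the analysis machinery,
not classifier performance on real diffusion MRI data.

A structural note on consensus recovery: with 50 features selected per
fold and 33 implanted, 17 selection slots per fold are filled by
noise-ranked edges, and across a 48-fold intersection typically 5–11 of
them are stable enough to enter the consensus set. Consensus precision
against the implanted truth therefore hovers around 0.75–0.85 by
construction of the selection rule, independent of how strongly the true
edges are implanted.

## Numerical and reporting choices

- Sizes used by the test suite and the acceptance script are scaled to the
  method's intended regime: 90-region, 22+26-subject cohorts for the
  recovery benchmark; 48-region, 10+10-subject cohorts (99 permutations,
  20 replicates) for null calibration; 200 subjects per group for
  calibration checks.
- All randomness flows through `numpy.random.default_rng` seeds; the CLI
  derives per-stage seeds from one global seed via `SeedSequence` and logs
  them. Identical configurations are bit-reproducible.
- Percentages are serialized at full precision and rounded to one decimal
  in human-readable reports; matrices are written as delimited text.
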