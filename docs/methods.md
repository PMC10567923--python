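# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `stresstraj`.

## Study design assumed by the pipeline

A session is three fMRI segments in fixed order: resting-state (155 volumes,
TR 2.5 s), a psycho-social stress task (755 volumes, TR 2.0 s), and a second
resting-state. The task holds 15 arithmetic blocks of 60 s (5 PreStress, 5
Stress with time pressure and negative feedback, 5 PostStress) interleaved
with 40 s fixation blocks; button presses and verbal feedback are auxiliary
events. The 15 task blocks plus the two resting states define 17 trajectory
"timepoints". `TaskDesign.compact()` shrinks block and fixation durations
(20 s / 6 s by default, ~200 task volumes) while preserving the 15-block
structure; simulation studies in the tests use it to keep runtimes in
seconds. A `TaskDesign` validates the block structure (15 task blocks, 5 per
phase, events within segment bounds).

## Timeseries preparation

Per segment, per ROI: linear detrend (a quadratic term is deliberately
omitted because the task's non-stress/stress/non-stress profile itself has
low-frequency structure); despiking by winsorizing samples further than
k = 4 robust SDs (1.4826 × MAD) from an 11-sample running median; projection
onto the orthogonal complement of the nuisance table (6 motion parameters,
their temporal derivatives, 5 + 5 physiological components, framewise
displacement), with numerically collinear nuisance columns dropped under a
warning; demeaning. The order detrend → despike → residualize → demean is a
package choice; the steps themselves are standard.

Concatenation matches baselines: the per-ROI mean over PreStress fixation
samples (all five fixation blocks of the PreStress phase) is subtracted from
the entire task segment, and each flanking resting-state is shifted so its
mean equals that baseline, which is zero. Matching only shifts segments, so
it is idempotent and preserves all within-segment differences. Task samples
outside labelled windows are annotated `task_fixation` or `gap` and are
retained in the series but excluded from block means.

## Per-edge hierarchical models

For an edge (ROI₁, ROI₂) — canonical order: upper triangle of the atlas
ordering, ROI₁ dependent — the design holds an intercept, 17 timepoint
indicators, the within-subject-centered ROI₂ series, the 17
indicator × ROI₂ interactions, and motor/feedback boxcars convolved with a
canonical double-gamma response (`gamma.pdf(t, 6) − gamma.pdf(t, 16)/6`,
peak-normalized). The 34 activation and interaction coefficients carry
participant random effects with a diagonal covariance: 35-dimensional
correlated random effects are not estimable from one session per subject,
and the diagonal structure factorizes the problem per term.

Estimation is the classic two-stage summary-statistics scheme: per-subject
OLS gives coefficients `b_i` with sampling variances `v_i`; per term, the
between-subject variance τ² is estimated by scalar REML for the
random-effects location model, and per-subject estimates are the
empirical-Bayes BLUPs `μ̂ + τ²/(τ²+v_i)·(b_i − μ̂)`. Under balanced designs
this coincides with the joint mixed-model solution (the test suite verifies
agreement with `statsmodels.MixedLM` on a balanced single-term problem:
τ² to 2%, BLUPs to 0.01), while remaining tractable for 210 edges × a full
cohort. A single-subject fit, or any fit with the random-effect variance
fixed very large (`tau2_override`), reduces exactly to that subject's OLS
coefficients — the no-pooling limit.

Two properties of this design worth knowing:

- Because interaction regressors are centered *globally* (not per block),
  their within-block means carry part of the block activation; per-subject
  activation estimates are therefore mildly attenuated relative to the
  generative effects (empirically a factor ≈ 0.7–0.9 depending on block
  length). Attenuation is uniform across subjects, so recovery correlations
  and downstream prediction are unaffected in rank terms.
- With dependent = first ROI of each canonical pair, the last ROI in atlas
  order is never dependent (dependent-model counts run 20…1, then 0). The
  atlas orders a bilateral ROI last, so every anatomical *region* keeps at
  least one dependent model; aggregation raises an error only if a region
  loses coverage.

Aggregation: activation — per ROI, average per-subject block estimates over
all models where the ROI is dependent, then over hemispheres (12 regions ×
15 task blocks = 180); connectivity — average interaction estimates over the
edges of each of 4 subnetworks (4 × 17 = 68). The default subnetwork map is
a deterministic anatomical partition (cortico-cortical /
subcortico-subcortical / cortical–limbic-hippocampal / cortical–striatal);
`cluster_edge_subnetworks` offers a seeded k-means alternative on group-mean
trajectories for data-driven maps.

## Prediction

Elastic net with mixing parameter 0.5 (fixed; exposed in config but not
searched), nested cross-validation: outer folds (default 10) give
out-of-fold predictions; within each training fold features are standardized
(training moments), outcome and features are residualized on the confounds
(training OLS), and the penalty is selected by inner-fold (default 10)
minimum MSE over a 100-point log-spaced path from the null-model penalty
down to 10⁻³ of it. Running the elastic net on confound-residualized data is
*exactly* equivalent to keeping the confounds as unpenalized columns
(Frisch–Waugh–Lovell profiling of the unpenalized block); the confound
coefficients are recovered afterwards so predictions include the confound
contribution. R² = 1 − SS_res/SS_tot on out-of-fold predictions, reported
as-is when negative. The baseline model is out-of-fold OLS on the confounds
with the same partition; ΔR² is the difference. Out-of-fold elastic-net
predictions are shrunken toward the training mean — a narrower predicted
range than observed is expected behaviour, not an error.

The permutation test shuffles (outcome, confounds) rows jointly against the
feature rows, so the outcome–confound correlation survives under the null;
each iteration redraws its own fold partition so partition variance
propagates into the null; p = (1 + #{null ≥ observed})/(B + 1). Defaults:
B = 1000 at the desk (the statistic is cheap to make stricter; study-scale
analyses would use 10,000).

Cross-sex transfer trains on one sex only (inner CV for the penalty, sex
dropped from the confounds), predicts the other, and reports the transfer
correlation and R² in both directions, alongside per-sex nested-CV results;
stratified training refuses groups under 10 subjects.

## Biomarker normalization and attribution

Cytokines: values below a marker's lower detection limit are set to zero and
values above the upper limit to the upper limit; markers with more than 16%
missing values are excluded; remaining values are mapped to standard-normal
quantiles via midranks, Φ⁻¹((r − ½)/n) (the plotting position ½ is a
documented constant); batch is regressed out per marker; residual missing
cells are median-imputed. Median imputation replaces a chained-equations
scheme deliberately: markers that survive screening carry very few missing
cells, and a hook (`imputer=`) accepts a richer imputer. Screening uses
partial correlation (residualize both sides on age, sex, diagnosis,
medication; t-based p on n − k − 2 df; verified against `pingouin`) at an
uncorrected p < 0.05 — selection only, no multiple-testing adjustment by
design.

Attribution regresses each selected marker on the observed, the out-of-fold
predicted, and the residual (observed − predicted) outcome with sex,
marker × sex, age, diagnosis and medication. The additive identity
observed = predicted + residual is exact per subject; orthogonality between
the components is *not* assumed or enforced. Note a structural consequence
of shrinkage: the predicted component systematically under-covers the
brain-visible outcome variance, so a genuinely brain-mediated marker retains
a small residual association (empirically significant in ~20% of cases at
n = 190 in the recovery experiments). The package therefore scores pathway
attribution by which component shows the *dominant* association, not by
demanding a null on the other component.

Distribution-matched resampling: weights on the group's outcomes are solved
by exponential tilting on (x, x²) — entropy balancing — so the weighted mean
and SD equal the reference moments exactly whenever they are feasible on the
sample's support; a density-ratio weighting cannot reach a reference SD much
wider than the group's truncated support allows, which is precisely the
male-to-female BMI case. `strength` interpolates between an ordinary
bootstrap (0) and full matching (1); weights are non-negative and sum to 1;
B weighted resamples (default 1000) recompute the statistic and report a
percentile interval plus the achieved moments.

## Stress markers

Affect: positive = sum of 5 items (activity, wakefulness, self-certainty,
focus, relaxed; range 5–30), negative = sum of 10 items (internal/external
agitation, anxiety, sadness, anger, dysphoria, sensitivity, 3 somatic items;
range 10–60); deltas at T6/T8 are taken against the pre-task baseline T3.
Cortisol deltas are taken against the pre-scanner sample T2; the pre-task
responder flag is T1 − T0 strictly greater than 2.5 nmol/l. IBI filtering
removes intervals outside [0.3, 2.4] s, then removes an interval only when
its relative deviation from the previous accepted interval, the following
interval, *and* the trailing 50-beat running mean all exceed the current
threshold; the threshold starts at 13% and is updated to twice the trailing
mean absolute successive relative difference, bounded to [0.13, 0.30] — the
update rule is a documented stand-in for an underspecified upstream
convention, exposed in the function signature. The deviation pass iterates
to a fixed point so the filter is idempotent. Block heart rate is
60/mean(IBI) bpm; phase contrasts average the five blocks per phase, with
unusable blocks dropped and empty phases missing. Association models are
OLS `response ~ BMI × sex + age + diagnosis + responder`; the joint
multivariate affect test is a MANOVA (Pillai's trace) on the four affect
deltas against the same design.

## Synthetic cohort: what it emulates and what it does not

BMI is drawn per sex from a truncated normal whose *truncated* moments equal
the stated values (the location/scale are solved numerically — using the
stated SD directly as the scale parameter would under-disperse the sample by
~20% given the stated ranges). BMI is split into two independent standard
normal components, z = √w·g + √(1−w)·h with brain-visible share w (default
0.5): planted trajectory effects load on g (and only in females when
`female_specific`, the default), "brain-mediated" markers load on g,
"independent" markers on h. This makes predicted/residual attribution
testable by construction.

ROI signals are level + slow drift + per-block boxcar activation (group
trajectory with a Stress-phase peak, between-subject SD 0.6, planted slope
per BMI SD) + edge coupling (the dependent ROI of each edge receives
coupling × the partner's intrinsic signal; coupling = baseline ≈ 0.15 plus
timepoint modulation, matching the regression structure the estimator
assumes) + nuisance leakage + white measurement noise (SD 0.5). Intrinsic
fluctuation SD is 0.6, chosen so per-subject boxcar OLS on a full-length
denoised session recovers planted deviations at r ≈ 0.9 — the reliability
regime in which subject-level trajectory modelling is meaningful.
Not emulated: autocorrelated (1/f) noise, haemodynamic convolution of the
block activation itself, spatial smoothness, scanner drift nonlinearity, and
session effects. Passing recovery tests therefore demonstrates estimator
correctness under the assumed regression structure, not robustness to every
property of real BOLD data.

Markers: cytokines are lognormal-like with a multiplicative batch effect,
5% missing completely at random, detection limits at the 2.5th/97.5th
percentiles; baseline (morning plasma) cortisol is clipped-normal with a
target BMI correlation of −0.27 (clipped-normal rather than lognormal so the
Pearson target is hit directly); the salivary series has a responder
pre-rise > 2.5 nmol/l by construction and a stress bump at T6; affect items
share one factor per scale (loading 0.6) with a BMI-scaled negative-affect
response in the planting group; IBIs realize a +6.7 bpm Stress heart-rate
increase with injected missed-beat and spurious-detection artifacts.

## Problem sizes in tests and the acceptance script

Planted effect magnitudes are free parameters of recovery experiments (no
study-reported values exist for them). The experiment drivers in
`stresstraj.experiments` use: structural counts at n = 4 subjects with the
compact design; recovery at n = 40, 6 ROIs, ~200 task volumes; permutation
calibration at n = 100, 20 features, B = 199, 200 replicate datasets with a
4×3 fold / 12-penalty configuration (calibration of an exact permutation
test does not depend on the model configuration); the sex-specific pattern
and attribution at the full cohort size (n = 190) with feature-level
simulation standing in for the timeseries→edge-model stage, since those
experiments test the prediction and decomposition stages. The attribution
experiment uses the identifiable regime (slopes ±1.5 on four regions,
w = 0.2, marker loading 0.6, effects in both sexes) described above.

## Known limitations

- The two-stage estimator ignores cross-term covariance of per-subject OLS
  errors; per-term REML is a quasi-likelihood simplification of the joint
  diagonal-G REML (excellent agreement in the balanced case; small
  differences expected under severe imbalance).
- Activation trajectory *levels* are attenuated by the centered-interaction
  collinearity described above; interpret features relatively, not in
  signal units.
- The permutation test redraws fold partitions per iteration; with very few
  outer folds the null acquires extra partition variance (conservative, not
  anticonservative — calibration is verified in the tests).
- Median imputation understates imputation uncertainty; use the imputer hook
  when missingness matters.
- The IBI threshold-update rule and the subnetwork map are documented
  package conventions, configurable by the user, not reproductions of any
  external tool's internals.
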