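# Methods

## Model and pipeline

`longimci` classifies progressive versus stable mild cognitive
impairment from longitudinal FDG-PET. The working assumption is that
conversion expresses itself as an accelerated loss of regional glucose
metabolism between baseline and follow-up, concentrated in
disease-relevant regions, while a single baseline scan of an MCI cohort
may show little group separation. The pipeline therefore builds three
feature families — static per-region intensities at each timepoint,
baseline-anchored dynamic changes, and cognitive scores — and compares
them under one common selection/classification protocol.

### Intensity normalization

PET intensities are in arbitrary units and must be normalized before
subjects can be compared. Global-mean scaling is biased when patients
are diffusely hypometabolic: dividing by a depressed global mean
inflates patient values everywhere and dilutes group differences. The
two-step reference-cluster procedure addresses this:

1. scale each image to its in-brain mean (exactly 1 afterwards);
2. for each voxel, a two-sample t-test of patients versus healthy
   controls; voxels with patient mean **above** control mean at
   one-sided p < α (default 0.05) form the reference cluster;
3. rescale each image to the mean intensity inside the cluster.

Choices the procedure leaves open, and how they are fixed here:

* **Sidedness.** The contrast is one-sided (patient > control). A
  two-sided test would also admit hypometabolic voxels, which would
  defeat the purpose of selecting preserved tissue.
* **Variance model.** Pooled (equal-variance) t by default, the
  classical voxel-map convention; Welch available via `equal_var=False`.
* **Per-timepoint clusters.** By default the cluster is re-estimated for
  each timepoint from that timepoint's patient images against the
  control baseline set; a single shared cluster is available
  (`per_timepoint=False`). Controls are imaged once, so the baseline
  control set is the comparison in both modes.
* **No multiplicity correction, no extent threshold** by default; an
  optional minimum connected-component size exists
  (`min_cluster_size`). Under the null the selected fraction is
  therefore ≈ α, which the test suite verifies by simulation.
* **Empty cluster.** An explicit `EmptyReferenceClusterError` is raised;
  the pipeline never falls back to global-mean scaling silently.

### Features

Static features are region means of the normalized images over an
integer-labeled atlas. Age and gender are removed by linear regression
on (intercept, age, gender). Because least-squares residuals are linear
in the response with a shared design, residualizing voxels and then
averaging within regions equals averaging first and residualizing the
region means; the implementation uses the region-level path and the
equivalence is verified numerically in the tests. Two residual forms
exist:

* `keep_mean=False` (function default): the pure residual, exactly
  orthogonal to the age and gender columns, mean zero;
* `keep_mean=True` (pipeline path): the fitted mean is added back, so
  only the centered covariate contributions are removed. This keeps
  normalized intensities near 1, which matters because the change rate
  `R_i = (T_bl − T_i)/T_bl` divides by the baseline value — pure
  residuals would center `T_bl` near zero and make R numerically
  meaningless. A guard rejects baselines below `eps` (default 1e-12).

Cognitive scores (MMSE, ADAS-cog at four timepoints) enter as-is; they
are not residualized. Confound regression is fit once on the whole
cohort before cross-validation (matching the stage order of the
pipeline); a leakage-safe analysis can instead residualize inside each
fold by extracting features with `residualize=False` and adjusting
per-fold.

Timepoints are fixed to `bl, m6, m12, m18`; the dynamic index i = 1, 2,
3 maps to the three follow-ups. The named feature sets follow the usual
benchmark layout: the four static blocks, `Static_all`, `Dynamic_1–3`,
`R1–3`, `Dynamic_all` (= the three D blocks; the R blocks are reported
separately), `Cognitive`, the pairwise combinations, and `All`.

### Selection and classification

The F-score of feature i is the squared deviation of the two class
means from the overall mean (over all samples, not the mean of class
means) divided by the sum of the within-class sample variances
(denominators n± − 1). It is invariant to per-feature affine maps and
blind to feature interactions. Ties in the ranking break by ascending
original index, so top-k selections nest. Features with zero variance
in both classes score 0 when the class means agree and +inf (flagged in
`FScoreResult.degenerate`) when they differ — possible with integer
cognitive scores in small folds.

Classification uses an RBF-SVM (C = 1, γ = 1/k by default, both
configurable; width may be given as σ with γ = 1/(2σ²)). No
hyperparameter search is run by default. Features are z-scored per fold
(standard practice for RBF kernels; `scale=False` disables it). The
evaluation is leave-one-out with the F-score ranking, scaling
parameters and SVM all refit on each fold's n−1 subjects. pMCI is the
positive class: SEN is the converter detection rate, SPE the
stable-MCI rate. The ROC curve is built from the pooled held-out
decision scores by sweeping all distinct thresholds; its trapezoidal
area equals the Mann–Whitney concordance probability with ties counted
one half (the tests verify both computations agree). The feature-count
sweep reports the full metric-versus-k curve and the accuracy-argmax k
(smallest k on ties); because that argmax is chosen on the same pooled
held-out predictions it is an optimistic model-selection convention,
and it is labeled as such.

The permutation control (`permutation_baseline`) reruns the LOO under
shuffled labels and reports, per permutation, the accuracy together
with its null expectation Σ_c P(pred = c)·P(y = c) computed from that
run's prediction frequencies. The RBF-SVM predicts both classes at
near-equal rates under the null, so this expectation sits near 50 %
rather than at the majority rate; leave-one-out additionally carries a
small negative bias (removing a subject from training tilts the
classifier toward the opposite class).

### Demographic statistics

Group comparisons of baseline covariates are computed from
(mean, SD, n) summaries: pooled-variance two-sample t with
df = n₁ + n₂ − 2, and Pearson chi-square without continuity correction
on the gender 2×2 table (Yates by flag). These conventions are the ones
consistent with the usual printed cohort tables in this literature.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not PET physics. Per voxel, intensity is

    I = B · g_ref · g_base · (1 − δ_g)^i + β_age(age − 70) + β_sex·sex + ε

with B the baseline mean (100), `g_ref = 1 − 0.05` for patients outside
the reference regions (the non-reference deficit that makes preserved
regions appear hypermetabolic after global-mean scaling), `g_base` an
optional group-specific baseline deficit in affected regions, δ_g the
per-timepoint fractional decline in affected regions (defaults 0.04
pMCI / 0.01 sMCI), and ε i.i.d. Gaussian voxel noise (SD 4). Age is
uniform on 55–85 with β_age = −0.3 intensity/year; gender is coded 0/1
with a +2 offset. MMSE falls and ADAS-cog rises linearly with
group-specific drifts around baselines typical of amnestic MCI, plus
visit-level noise. Healthy controls receive baseline images only, since
they enter the pipeline solely as the normalization comparison set.

The atlas is a deterministic partition of the grid into contiguous
near-equal runs along a serpentine voxel path, with label ids permuted
by the seed; the brain mask is the full grid. Default scale: 18×18×12
voxels (≈16 voxels per region at 246 regions) with 46 + 33 + 20
subjects, which keeps a full pipeline run near one second.

What the generator does **not** emulate: scanner point-spread and
partial-volume effects, spatially correlated noise, anatomically shaped
regions, registration error, missing visits, and floor/ceiling effects
in cognitive scores (trajectories are linear-Gaussian and unclipped).
Passing tests therefore demonstrate that the pipeline recovers the
planted statistical structure under its own assumptions — not that the
same accuracies would be attained on real scans.

## Numerical and design notes

* Every stochastic component draws from `numpy.random.default_rng`;
  one global seed fans out to stage seeds via `SeedSequence.spawn`, so
  identical configurations reproduce bit-identical cohorts and metric
  tables.
* Percent metrics are kept at full precision internally and rounded to
  two decimals (AUC to four) only in `CVResult.summary()`.
* Zero-SD columns in per-fold scaling are left unscaled (divisor 1)
  rather than producing NaNs.
* Degenerate inputs raise informative errors rather than being patched:
  non-positive global or reference means, empty regions under the brain
  mask, rank-deficient confound designs, single-class folds, empty
  reference clusters.
* Constant decision scores yield AUC 0.5 with a warning, not an error.

## Known limitations

F-score selection ignores feature interactions and redundancy, so
combined feature sets can underperform their best member. The
whole-cohort confound regression and the accuracy-argmax k are mild
optimism sources retained deliberately to mirror the classical
protocol; both have leakage-safe alternatives noted above. Leave-one-out
metrics at n ≈ 80 have high variance — single-digit accuracy
differences between feature sets are not individually meaningful, which
is why the tests assert orderings under strongly planted effects rather
than absolute values.
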