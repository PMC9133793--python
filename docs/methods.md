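# Methods

`oddwave` reimplements, end to end, the analysis pipeline of a roving-oddball
MEG decoding study: from experimental-design generation and synthetic epoch
simulation through time-resolved multivariate decoding to cluster-corrected
permutation inference and latency bootstraps.  Because no recordings ship
with the package, the synthetic-data generator is a first-class module with
known ground truth, and every downstream stage is validated against it.

## Experimental design

The paradigm presents 600 consecutive "trains" of 4, 5 or 6 identical
consonant-vowel syllables (200 trains of each length; 3,000 trials total;
stimulus-onset asynchrony 575 ms, syllable duration 310 ms).  Five stimuli
A-E are drawn from a 10-step /ba/-/da/ continuum: a 4-parameter logistic
(asymptotes constrained to [0, 1], least squares) is fitted to a listener's
labeling ratios, stimulus C is the continuum step nearest the inflection
point (clamped, with a flag, so the equidistant set fits the continuum), and
A, B, D, E sit at +-2 and +-4 steps around C.

The train sequence must satisfy: consecutive trains differ in stimulus,
every ordered stimulus transition occurs, and transition counts are
near-equal.  With 600 trains there are 599 transitions over 20 ordered
pairs, so exact equality is impossible; we realize counts within +-1 of
599/20 by construction.  The generator builds a directed multigraph on the
five stimuli with q = floor(599/20) = 29 parallel edges per ordered pair
plus a 19-edge remainder trail (an Eulerian circuit of the complete digraph
minus its last edge), and emits a seeded Eulerian path through it
(Hierholzer's algorithm with shuffled adjacency).  This yields exactly the
published count structure - 600/600/600/600/400/200 trials at positions 1-6,
transition counts of 29 or 30, and 120 trains headed by each stimulus -
deterministically for any seed, with no rejection sampling.  Train lengths
are a uniform seeded shuffle of the 200/200/200 multiset; the length order
is otherwise unconstrained.

## Synthetic epochs

Epochs span -200..550 ms (default 1,000 Hz; coarser grids are used
throughout the test suite) over a 306-sensor layout (102 magnetometers, 204
planar gradiometers; both counts scale down proportionally for smaller test
arrays).  Each trial is a low-rank spatiotemporal pattern plus noise:

    x(trial) = common + m_k * A * (1 + jitter) * deviance + drift + noise

* **common component**: a unit-norm random topography times a gamma-shaped
  kernel (onset 30 ms, peak 100 ms, amplitude 250 units) - the generic
  auditory evoked response, identical for all trials.
* **deviance component**: a second, orthogonal unit-norm topography times a
  gamma kernel with onset 100 ms and peak 280 ms.  `A` = 60 units by
  default; `jitter` is a per-trial N(0, 0.2) amplitude perturbation.
* **attenuation profile** `m_k` (k = position in train, the experimental
  variable): `control` = {1, 0.6, 0.4, 0.2, 0.12, 0.08} (standardness
  accrues with repetition), `dyslexia` = {1, 0.4, 0.4, 0.4, 0.4, 0.4}
  (immediate but flat), `null` = all ones (no condition information).
* **noise**: spatially correlated Gaussian noise, covariance built from a
  random orthogonal mixing of exponentially decaying eigenvalues (condition
  number 100, unit average sensor variance), scaled by 100 units - so
  whitening is consequential.
* **drift**: a per-train random topography times a smooth random time course
  (mix of a ramp and a half-sine), SD 100 units, shared by every trial of a
  train.  This emulates the slow, shared low-frequency activity of real
  recordings and is what makes tiny same-train contrasts behave like the
  real data (below).

Amplitudes are in nominal fT-scale units: single-trial peak-to-peak stays
far below the artifact-rejection thresholds, and the deviance amplitude is
calibrated once so that a default synthetic cohort's deviant-vs-all-standards
group accuracy peaks in the 60-80% band that the study-scale analyses report.
Because pseudo-trial averaging scales SNR with trial count, the amplitude
that lands in that band depends on the design size; the default (60 units)
is calibrated at the reference reduced scale used by the test suite, and
analysis drivers that run the full 600-train design carry their own
calibration constant in their config (16 units at 600 trains / 64 sensors)
rather than a hard-coded override of the model.
All randomness flows through one `numpy` generator per simulation call, so
outputs are bitwise reproducible given a seed.

Artifact trials are emulated by adding a single-sample spike (default twice
the rejection threshold for the sensor's type) to a random sensor in a
random subset of trials; the corrupted indices are returned so rejection can
be tested against an oracle list.

## Preprocessing

Order is fixed and enforced through the container's normalization-state
flag: reject -> filter -> baseline-normalize.

* **Rejection**: a trial is dropped if any magnetometer exceeds 10,000 fT or
  any gradiometer 2,500 fT/cm peak-to-peak (computed over the full epoch),
  or if all samples are exactly zero.
* **Low-pass**: zero-phase Hamming-window FIR at 15 Hz, 5 Hz transition band
  (delegated to MNE's `filter_data`).  Zero-phase filtering avoids latency
  bias, which the latency analyses require; only the cutoff behavior is
  asserted by tests, since the filter family is a convention.
* **Baseline z-normalization**: per trial and per sensor, subtract the
  -200..0 ms mean and divide by its SD.

## Decoding

Per participant and contrast: trials are assigned to 5 stratified folds
(seeded permutation + round-robin within condition; requires at least
`n_folds` trials per condition).  A noise covariance is estimated on the
training folds only with the "epoch" method - per time point and condition,
the across-trial covariance of (trial - condition mean), averaged over time
points then conditions - shrunk toward its diagonal with an analytically
chosen intensity (a Ledoit-Wolf-style optimal gamma computed from the pooled
residuals; a fixed gamma can be forced for tests), and inverted (eigen
inverse square root) into a whitener applied to training and test trials
alike.  Within each fold, trials of a condition are averaged into one
pseudo-trial; at every time point a linear C-SVM (C = 1) is trained on the
2(k-1) training pseudo-trials and tested on the 2 held-out ones.  Accuracy
is averaged over folds, then over 100 (default) repetitions of the random
fold assignment.  Class imbalance (e.g. 600 deviants vs 2,400 standards) is
neutralized only by the pseudo-trial averaging, as in the original scheme.

The SVM is solved in-package by a batched SMO dual solver vectorized across
time points (`oddwave._svm`); it solves the identical C-SVM dual as libsvm
and is cross-checked against sklearn's `SVC` in the test suite.  The batch
formulation is what makes the permutation/power suites tractable: one
decoding run performs on the order of 1e5 eight-sample fits.

Temporal generalization reuses the same engine on a grid decimated by 4
(after the 15 Hz low-pass, so no aliasing), training at each time point and
testing at all of them; its diagonal is bit-for-bit the time-resolved
analysis on the same grid and seed.

Statistics are evaluated on 0-550 ms only; the full epoch is decoded and
stored.

## Inference

* **One-sample sign-permutation cluster test**: the statistic map is the
  across-subject mean deviation from the null value (0.5 for accuracies, 0
  for differences).  Permutation samples flip each subject's whole series
  by +-1 about the null; pointwise p-values are empirical ranks within the
  5,000-sample distribution (observed sample included, so p >= 1/5,000 =
  0.0002); clusters are maximal contiguous runs with pointwise p <= 0.05;
  cluster mass is the sum of the statistic within the run; the corrected p
  of a cluster is the fraction of per-permutation maximal masses at least as
  large.
* **Two-sample test**: difference of group means, null built by random
  reassignment of subjects to groups of the original sizes; a paired
  sign-flip-of-differences variant serves within-subject comparisons (the
  ordered repetition contrasts 1v3 > 1v2, 1v4 > 1v2, 1v4 > 1v3 are one-sided
  paired tests on per-subject accuracy differences).
* **Latencies**: onset = first time point of the earliest corrected-
  significant cluster (no extra minimum-duration rule); peak = argmax of the
  group-mean series in 0-550 ms.  Group or condition differences are tested
  by bootstrapping subjects with replacement (1,000 draws by default; paired
  comparisons resample jointly), recomputing the latency per draw, and
  taking p = 2 * min(P(diff <= 0), P(diff >= 0)) over defined draws; draws
  with undefined onsets are dropped and the result is flagged unreliable if
  they exceed half.
* **Behavioral table**: two-sample pooled-variance t and Cohen's d with the
  pooled SD; the packaged assessment table reproduces every printed t and d
  within 0.010 and 0.005 respectively.

## Study orchestration

`run_full_study` fans a master seed out through `numpy.random.SeedSequence`
(design seed, per-subject simulation seeds, one seed per decode and per
test), simulates `n_per_group` participants per profile on a shared design,
preprocesses, decodes all contrasts plus the subset control (standards
subsampled to the usable 6ths count, per the original procedure) and the
stimulus-specific grid, then runs the inference battery.  Two runs with the
same config produce hash-identical reports.

The stimulus-specific 5 x 5 grid pairs the 4th-position standards of each
stimulus (120 trials) with each possible successor: its own 5ths
(same-stimulus cell) or the deviants of another stimulus that directly
follow a length-4 train of it.  The latter conditioning reproduces the
published cell sizes (at most ~14, as few as 5 usable trials per deviant
cell); cells with fewer trials than folds are reported as undefined.

## Known small-scale behaviors and limitations

* **Count-imbalance bias at few sensors.**  With unequal per-class trial
  counts, per-class pseudo-trials have unequal variances, and the
  soft-margin SVM's intercept converts that asymmetry into systematic
  above-chance accuracy on null data when the sensor count is small (about
  57% at 32 sensors with a 1:4 imbalance; verified identically with libsvm).
  The effect vanishes at the full 306-sensor array, which is consistent with
  chance-level prestimulus baselines at study scale.  Consequently the
  chance-calibration tests use balanced contrasts, and the reduced-scale
  subsetting comparison subsets both classes.
* **Below-chance small-sample decoding.**  With independent trials,
  cross-validated accuracy is exactly unbiased at chance, so the published
  below-chance regime for same-stimulus 4ths-vs-5ths at tiny trial counts
  requires inter-trial dependence.  The per-train drift term provides it:
  a held-out trial shares its train's drift with training trials of the
  opposite class, which pushes cross-validated accuracy below 50% exactly
  when trial counts are small.  The package reproduces this regime at
  matched counts (~16 per class).
* **Temporal-generalization asymmetry.**  The reported asymmetry (training
  on high-SNR data and testing on low-SNR data outperforming the converse)
  does not emerge from this generator: for a fixed spatial pattern whose
  amplitude ramps over time, accuracy behaves like
  Phi(k * s_test * cos(theta_train)) with the weight-alignment term
  cos(theta_t) increasing in the training-time separation, which always
  favors the converse direction under symmetric pseudo-trial averaging.
  Reproducing the asymmetry would require pattern dynamics or noise
  nonstationarity that the low-rank model deliberately omits.
* The generator makes no biophysical claims: no forward model, no sensor
  geometry, no temporal autocorrelation within the noise (the decoder treats
  time points independently), no continuous-recording artifacts.  Passing
  tests demonstrate the correctness and calibration of the pipeline, not
  properties of real MEG data.

## Problem sizes

Unit and acceptance suites run at reduced scale as the package's reference
configuration: 24-32 sensors, a 50 Hz epoch grid, 40-60-train designs,
2-5 fold-assignment repetitions, and 300-5,000 permutations depending on the
test; the cohort-level calibration suites use 50 seeded cohorts of 8
participants per profile.  The analysis drivers use intermediate scales
(64 sensors, 100 Hz, the full 600-train design) and the configuration
defaults are the full-study values (306 sensors, 1 kHz, 100 repetitions,
5,000 permutations, 1,000 bootstraps).
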