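# Methods

`specdecode` implements a complete analysis chain for asking whether the
aperiodic (1/f-like) and oscillatory components of epoched M/EEG activity
carry information about task state, and whether that information
generalizes across tasks. Because suitable public recordings with the full
3 tasks x 2 contents x 2 demands design are not generally available, the
package ships a synthetic-data generator with known ground truth; every
stage is validated against that ground truth, against closed-form oracles,
or against independently coded reference implementations.

## Synthetic cohorts

The generator emulates a stimulus-locked cognitive-control recording:
epochs from -1 to 2 s at 200 Hz, channels of three kinds (EEG in volts,
magnetometers in tesla, gradiometers in T/m, with distinct nominal scales
so that standardization is consequential), and twelve condition cells
(task in {WM, SWIT, MSIT} x content in {alphanumeric, colour} x demand in
{easy, hard}).

Each epoch and channel receives:

- **Aperiodic background** — unit-variance noise with power spectrum
  proportional to 1/f^chi, synthesised by spectral shaping of Gaussian
  white noise (rFFT, multiply amplitudes by f^(-chi/2), inverse rFFT,
  renormalise). The per-subject exponent is drawn from a normal
  distribution (default mean 1.5, sd 0.2, a typical cortical range).
- **Oscillations** — sinusoids with uniformly random phase per epoch and
  channel (hence non-phase-locked: they survive evoked subtraction and
  cancel in trial averages) and per-trial frequency jitter of
  +-bandwidth/2 around the centre frequency. The default is a single
  alpha-band component at 10 Hz.
- **Evoked transient** (optional) — a Gaussian-windowed bump identical in
  every epoch, i.e. perfectly phase-locked.
- **Sensor noise** — white noise at a configurable floor (default 0.1 of
  the background's unit variance).

Condition effects are multiplicative and routed through per-channel maps
with weights in [0, 1]: in the *hard* (or *colour*) condition the
aperiodic amplitude on channel c is scaled by `1 + w_c (F - 1)` and the
exponent shifted by `w_c * delta`. The default demand effect is a
broadband amplitude factor of 0.8 (hard < easy, i.e. reduced aperiodic
broadband power under demand; amplitude squares into power, so mapped
channels lose 36% of their power), and the default content effect is a
milder 0.9 on an independent map. Effect sizes in physical units are free
parameters of the simulation, not calibrated to any particular dataset.
Every factor actually applied is recorded in a `GroundTruth` object used
by the recovery tests.

Default cohort size is 20 subjects x 24 trials per condition x 64
channels — large enough for the group analyses below while keeping a full
run on one CPU in minutes. All randomness derives from a single seed: one
`SeedSequence` stream per (master seed, tag...) combination, where tags
name the subject, stage, repetition etc., so runs are bit-reproducible and
independent of execution order.

What the generator does **not** emulate: realistic sensor geometry or lead
fields (channel maps are abstract mixing weights), correlated sensor
noise, artifacts (blinks, cardiac), non-stationarity within an epoch, or
spectral knees. Passing tests therefore demonstrate correctness of the
*analysis machinery* under the stated generative model, not robustness to
every property of real recordings.

## Preprocessing

Three operations, applied to already-cleaned epochs (raw-data steps such
as SSS, ICA and filtering are out of scope):

- **Peak-to-peak rejection** drops an epoch when any channel exceeds its
  kind's threshold (defaults 350 uV EEG, 5000 fT magnetometers,
  4000 fT/cm gradiometers). Idempotent by construction.
- **Evoked subtraction** removes the trial-mean timeseries within each
  (subject, task, content, demand) cell — the finest labelled cell, so
  condition-mean differences cannot survive as phase-locked residue. A
  cell with one epoch raises (subtraction would zero the trial).
- **Cropping** to the analysis window, by default 0.3-1.5 s after
  stimulus onset. Windows are half-open `[start, end)` with sample i at
  `t0 + i/fs`, giving exact sample counts (240 at 200 Hz).

## Spectral separation (IRASA)

For each resampling factor h in {1.10, 1.15, ..., 1.90} the epoch is
resampled to round(n*h) and round(n/h) samples with the Fourier method and
both series are *reinterpreted at the original rate*: upsampling
compresses spectral content to f/h, downsampling stretches it to f*h. A
power-law spectrum is invariant under the geometric mean of the two branch
spectra, while narrow-band peaks are displaced and removed by the median
across the h set. The aperiodic estimate is subtracted from the mixed
spectrum to give the (signed) oscillatory component. The highest estimable
frequency is fs/(2*h_max) = 52.6 Hz at 200 Hz; the default analysis grid
is 1-30 Hz in 1 Hz steps.

Numerical choices:

- **PSD estimator**: a single Hann-tapered modified periodogram per
  epoch, zero-padded so that the requested grid frequencies are exact FFT
  bins whenever they are commensurate with fs (trigonometric rather than
  linear interpolation; linear interpolation of chi^2-noisy bins leaves a
  grid-phase ripple).
- **Small-sample debias**: each branch is the geometric mean of two
  single-taper estimates whose bin values are approximately chi-squared
  with 2 dof; since E[sqrt(X)]^2 = pi/4, the raw geometric mean
  underestimates the spectrum by that factor and is multiplied by 4/pi.
- **Median vs mean across h**: the default is the median, which is what
  keeps genuine oscillatory peaks out of the aperiodic estimate (with the
  default 1.2 s epochs, a 10 Hz oscillation moves the fitted slope by
  less than 0.1). The cost, at single-epoch statistics, is a
  frequency-dependent positive residue in the oscillatory component of up
  to ~30% of the aperiodic level under pure noise (the median of many
  nearly independent skewed branch values sits below their mean). Mean
  aggregation (`h_aggregate="mean"`) is unbiased in that situation but
  leaks peaks; both are tested at their measured levels. The residue is
  common-mode across experimental conditions and does not affect decoding
  contrasts or slope recovery at the tolerances stated below.

Six per-trial signals are extracted per channel: aperiodic broadband power
(mean aperiodic power over 3-30 Hz), slope and intercept of an ordinary
least-squares line fitted to log10 power vs log10 frequency over 3-30 Hz
(the intercept is the fitted log-power at 1 Hz), and mean oscillatory
power in theta (3-7 Hz), alpha (8-12 Hz) and beta (15-30 Hz). The 13-14 Hz
gap between alpha and beta is intentional. Oscillatory band means keep
negative values: truncation at zero would bias the decoding features. The
fit range for slope/intercept matches the broadband definition (3-30 Hz);
spectra are computed per epoch because decoding needs single-trial
features — averaging raw series first would cancel the non-phase-locked
oscillations.

Verified properties: exact scale equivariance (input x k => power x k^2,
intercept + 2 log10 k, slope unchanged); slope recovery within +-0.2 over
chi in {0.5, 1, 1.5, 2}; log-spectrum correlation > 0.99 with an
independently coded reference (polyphase resampling, boxcar periodograms)
on epoch-averaged spectra — per-epoch correlations saturate near 0.97
because the two estimators carry independent chi^2 noise.

## Decoding

Binary contrasts (hard vs easy per subtask; alphanumeric vs colour per
task, optionally easy trials only) are decoded per subject and signal:

1. **Pseudo-trials**: within each class, trials are randomly grouped in
   fours and averaged; remainders are dropped and class counts equalised
   by random removal from the larger class.
2. **Standardization**: per-feature z-scoring with training-set statistics
   only; zero-variance features are dropped with a logged warning.
3. **PCA** on the training portion, keeping the smallest number of
   components reaching 99% cumulative explained variance; the test
   portion is projected onto the same basis.
4. **Linear SVM** (C = 1, tight convergence tolerance 1e-8 so that weight
   back-projection is numerically exact); performance is the AUC of the
   continuous decision values.
5. **Stratified 5-fold CV**, the whole procedure repeated 25 times with
   fresh pseudo-trial draws, and AUCs averaged.

Cross-task generalization trains on *all* pseudo-trials of one subtask
(standardization and PCA fitted on the training subtask only) and tests on
another; the reported matrix averages the two directions of each pair,
with within-subtask decoding on the diagonal.

Calibration was verified empirically: on null cohorts the decoder's group
mean AUC is 0.50 and the one-tailed group t test rejects at ~4-5% at
nominal alpha = 0.05.

## Activation patterns

Linear classifier weights are extraction filters; multiplying them by the
feature covariance (Haufe forward projection) yields the pattern of signal
the classifier tracks, proportional to the class-mean difference for
equal-covariance Gaussian classes. The projection uses the covariance of
the standardized pseudo-trial features the classifier was fitted on, with
the weights expressed in that same space; patterns are normalized to unit
norm (they are defined only up to positive scale). Sign convention:
classes are ordered alphabetically and positive values mean greater signal
in the second-named class — *hard* for demand, *colour* for content,
which matches the convention of reporting increases under demand as
positive.

Group maps z-score each pattern across features, then average across
subjects and subtasks. Note that z-scoring recentres each pattern: with
half the channels modulated downward, unmodulated channels end up on the
positive side of the group map; the modulated set still ranks lowest.
Display thresholding keeps features whose |value| reaches a percentile of
all |values| (default 60th), retaining signs; ranking is on absolute
values because group maps contain meaningful values of both signs, and
ties at the threshold are all retained.

## Inference

- Per-subject AUCs are tested against 0.5 with one-sample t tests,
  one-tailed (below-chance decoding is uninterpretable), and
  Benjamini-Hochberg FDR correction within each analysis family.
- Spatial similarity between patterns (e.g. theta vs alpha demand maps)
  is the mean across participants of the within-participant Pearson
  correlation over features. Its significance comes from a permutation
  test: each of K iterations (default 1000) shuffles the feature order of
  one pattern independently within every participant and recomputes the
  mean r; p = (1 + #{|null| >= |observed|}) / (K + 1), the add-one
  estimator that never returns zero. The test is two-tailed on |mean r|
  because positive and negative correlations are both interpretable.

## Condition geometry

Per subject and signal, trials are averaged within each condition cell;
per task, the 4 condition means (content x demand) are projected onto
their first two principal axes. Task embeddings are superimposed by
Procrustes alignment restricted to rigid transforms — centering plus an
orthogonal rotation/reflection, *no scaling* — and averaged; subject
embeddings are then aligned to the first subject (by sorted ID, for
determinism) and averaged. Rigid alignment preserves within-configuration
pairwise distances to machine precision. Reflections are allowed (the
full orthogonal group), the standard Procrustes solution. PCA is fitted
per task before alignment rather than once on all 12 conditions.

## Problem sizes used by the test suite

The acceptance-style checks run end-to-end at desk scale on one CPU:
exponent recovery uses 200 epochs x 64 channels; the null-calibration
cohort uses 20 subjects x 72 trials/class x 16 channels at 25 repetitions,
with the 50-cohort false-positive-rate check at 20 trials/class x 8
channels and 5 repetitions; effect detection uses 20 subjects x 36
trials/class x 16 channels; cross-task transfer uses 8 subjects x 24
trials/class x 16 channels. For these calibration cohorts the epochs are
simulated directly inside the 1.2 s analysis window (evoked subtraction
and cropping have dedicated checks of their own). These sizes are the
package's choice of a desk-scale experiment; all thresholds they are held
to are stated in the tests themselves.

## Known limitations

- Single-epoch IRASA at 1.2 s has coarse native resolution (0.83 Hz) and
  chi^2_2 bin statistics; the median-across-h residue discussed above is
  the practical consequence. Long-window or multi-segment PSDs would
  reduce it but are not what a per-trial decoding pipeline can use.
- The straight-line aperiodic fit has no knee/bend term; spectra with a
  knee inside 3-30 Hz would bias slope and intercept.
- The generator's channel maps are abstract; no claim is made about
  anatomical localisation, and "source patterns" here simply means
  feature vectors indexed by ROI names.
- Pseudo-trial counts limit the resolution of per-subject AUCs; group
  statistics carry the inferential weight.
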