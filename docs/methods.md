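# Methods

## Analysis model

The quantity being explained is the trial-by-trial amplitude of the motor
evoked potential (MEP), measured peak-to-peak (mV) in the EMG between +20
and +40 ms after a TMS pulse and log-transformed to reduce right skew.  The
predictors are characteristics of the pre-stimulus sensorimotor beta
rhythm, extracted from a single analysis channel — the Hjorth transform of
C4 (C4 minus the mean of FC2, FC6, CP2, CP6) — in the −1 to −0.05 s window
before the pulse:

* **event presence** (0/1) and **event number** per trial;
* **last-event maximum amplitude** (normalized power units) and
  **half-max duration** (s);
* **last-event timing**: latency of the last event's power peak before the
  pulse, in positive seconds (larger = earlier).  With this sign
  convention, a *negative* model estimate means MEPs are larger when an
  event occurred closer to the pulse;
* **mean beta power**: mean normalized power over the window, events or
  not.

For each metric *m* a linear mixed model is fit by maximum likelihood:

    log MEP_ij = beta0 + beta1 * m_ij + u_i + eps_ij,   u_i ~ N(0, s_u^2)

with a random intercept per subject *i*.  Estimates are reported with Wald
95% CIs and back-transformed to percent MEP change per unit metric,
`(e^b − 1)·100`.  Whether an event characteristic explains variance beyond
mean power is tested by a likelihood-ratio test between the mean-power
model and the model with both fixed effects (chi-square, df = 1), on the
identical trial set.  Predictive performance is assessed by 10-fold
cross-validation with per-subject 90/10 splits: per fold, the model is
refit on the training trials and test trials are predicted from the fixed
effects plus the subject's fitted random intercept; performance is the
fold-mean Spearman correlation between predicted and observed log MEP and
the fold-mean RMSE divided by the observed log-MEP range.

Event-conditional metrics (number, duration, amplitude, timing) are
modeled on trials containing at least one event; event presence and the
all-trials mean-power model use every retained trial.

## Beta power and event definition

Per subject, the individual beta frequency (IBF) is the 15–30 Hz argmax of
the multitaper PSD (Slepian tapers, ±2 Hz smoothing) of the pre-stimulus
data, averaged over retained trials.  The study this emulates identified
the IBF visually; the deterministic argmax is used here for
reproducibility, and an argmax on the band edge is flagged with a warning.

The beta power series is the squared magnitude of a 5-cycle complex Morlet
wavelet at the IBF.  To avoid edge effects at the pulse, the pre-stimulus
segment is extended by its own time-reversed reflection about t = 0 before
convolution, then cropped to the analysis window.  Within the window
(−1 to −0.05 s, i.e. ≥ 10 wavelet standard deviations from the segment
ends after mirroring) the padding choice is irrelevant to < 1e−6 relative
error, which the test suite asserts.

Normalization divides each subject's power series by the mean raw power
over that subject's retained trials and window samples, so normalized
power is dimensionless with per-subject grand mean exactly 1.  The pool is
per subject, not per trial: per-trial normalization would erase the
between-trial power differences that the mean-power model relies on.

Events are maximal runs of samples **strictly above** a per-subject
threshold — the empirical percentile (linear interpolation between order
statistics, so the 75th percentile of {1..100} is 75.25) of the pooled
window samples across the subject's retained trials.  Runs shorter than
1.5 cycles at the IBF are discarded.  Two thresholds are carried through
the whole analysis (75th percentile, and an empirical threshold chosen as
the percentile in 50–98 at which the subject-mean Pearson correlation
between time-in-events and mean power peaks) to show threshold robustness.

**Durations.**  An event's duration is the time its power exceeds half of
its maximum, measured on the piecewise-linear interpolant of the samples
and confined to the event's run — so a rectangular pulse of width w gives
w, a symmetric triangle of base b gives b/2 and a sampled Gaussian gives
2.355·sigma to within a sample step.  A run touching a window boundary is
an event only when its power maximum is interior (power already declining
at the edge); its duration is twice the half-max time on the side of the
peak that lies inside the window.  With several supra-half lobes inside
one run, the lobe times add.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's stated conditions: 32-channel EEG epochs (−3 to +3 s, 5 kHz),
beta events at 1.24 per second lasting ~114 ms (half-max), IBFs inside
15–30 Hz, and one MEP per trial.

* **Bursts**: amplitude-modulated sinusoids at the subject IBF with Hann
  amplitude envelopes (chosen for compact support and a well-defined
  half-max width; the envelope full width is the drawn half-max duration
  divided by 0.3639) and lognormal peak amplitudes (median 6 µV, log-sd
  0.25 — the emulated study reports no amplitude distribution, so it is
  exposed as configuration).  Bursts ride on 1/f background noise (8 µV
  RMS per channel) on C4 only; other channels carry background noise.
* **Timing**: events occur throughout the pre-stimulus period; counts in
  the analysis window are Poisson(rate × window length).  Peaks keep a
  minimum separation of 0.25 s (about one envelope width): events closer
  than a burst width are not identifiable as separate events by any
  threshold detector, so a hard core is the only way the injected and
  detected counts can agree.  Placement is exactly uniform conditional on
  the count (spacings construction); counts above the packing limit
  (probability ≈ 0.6% at the defaults) are capped.
* **MEPs**: a fixed biphasic template in +20 to +40 ms with unit
  peak-to-peak, scaled so that log amplitude = global intercept + subject
  intercept + Σ coupling·metric + Gaussian noise, metrics taken from the
  injected events.  Default coupling is mean power alone (b = 0.07):
  because all event metrics are collinear with mean power, this single
  coupling reproduces the qualitative structure of interest — every event
  metric predicts MEP amplitude, and none adds variance beyond mean power.
  The residual sd (0.4) and subject-intercept sd (0.3) are set so that the
  effect size relative to noise and the between/within variance ratio
  match the reported fixed-effect standard errors and cross-validated
  correlations of the emulated study.
* **Contamination**: a configurable fraction of trials receives > 50 µV
  pre-stimulus EEG transients (exercising the rejection rule) and a
  fraction receives sustained strong EMG (exercising both EMG filters).

What the generator does **not** emulate: volume conduction and realistic
scalp topography (bursts live on one channel), TMS pulse artifacts,
non-stationary background spectra, mu/gamma bursts, and any nonlinearity
in the metric→MEP coupling.  Passing tests therefore show that the
pipeline recovers the planted structure under its own assumptions, not
that those assumptions hold in recordings.

## Numerical choices

* Kurtosis in artifact rejection is the Pearson convention (Gaussian ≈ 3),
  so the > 4 rule is an exceedance above Gaussianity; the amplitude rule is
  applied to the Hjorth (analysis) channel on [−1, 0) s.
* Supra-threshold is strict (`>`); ties count as below.
* Mixed models are always fit by ML (not REML) so LRTs and AIC
  comparisons across fixed-effect structures are valid.  AIC is
  −2·ll + 2·(fixed effects + variance parameters).
* A singular random-effects fit falls back to pooled OLS with a warning
  and is flagged in the results; with zero between-subject variance the
  estimate then equals the OLS slope exactly.
* When the fitted residual variance collapses to the zero boundary
  (exactly deterministic data), estimates are refined to the
  within-subject estimator — the analytic limit of the ML solution —
  because the iterative optimizer alone leaves ~1e−5 prediction error.
* Cross-validation predictions include the subject's random intercept by
  default (subjects appear in train and test by design of the per-subject
  split); a fixed-effects-only mode exists and is the appropriate null
  for permutation checks, since intercepts fitted to permuted labels are
  anti-correlated with the held-out labels (train and test partition each
  subject's fixed label set).
* Fold assignment is a seeded per-subject shuffle with balanced labels
  (`i mod k`), recorded in the CV result; 20 trials/subject at k = 10
  yields exactly 2 test trials per subject per fold.

## Problem sizes

Full-waveform simulations in the test suite and the acceptance script use
scaled studies (3–8 subjects × 24–150 trials at 1–2 kHz with the five
analysis channels); statistical calibration studies use the fast
metrics-only generator path at up to 20 subjects × 300 trials with
hundreds of replicates.  All scientific parameters (rates, durations,
couplings, thresholds, windows) stay at the defaults above regardless of
scale.

## Known limitations

* The detector counts threshold crossings; background fluctuations that
  stay supra-threshold for ≥ 1.5 cycles are events by definition, so
  detected rates slightly exceed injected rates at percentile thresholds.
* The empirical-threshold curve uses Pearson correlations of bounded
  fractions, which become degenerate at extreme percentiles for subjects
  with few events; such subjects drop out of the mean with a warning.
* Wald CIs and z-based p-values are used throughout (no Satterthwaite or
  profile corrections); at very small subject counts their calibration is
  approximate, which the type-I-error test bounds empirically.
* Real-data mode is limited to whatever epoched arrays the caller
  provides to `TrialSet`; no raw-format readers are bundled.
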