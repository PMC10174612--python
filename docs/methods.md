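# Methods

`neuroglyc` implements an analysis pipeline linking multi-channel intracranial
powerband activity to continuous interstitial glucose over multi-day
recordings, together with a synthetic-data generator that makes every stage
testable against known ground truth. This note documents the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## Signals and timebase

Neural input is a channels × time voltage matrix (µV) at a stated sampling
rate (clinical stereo-EEG is typically 1024 Hz), with per-contact metadata
(electrode shaft, contact index, anatomical region, gray/white tissue).
Glucose is an interstitial CGM series (mg/dL) at nominal 5-min cadence.
All timestamps are absolute; time of day is derived from them for circadian
controls.

CGM gaps of at most 3 consecutive points are filled by linear interpolation
between the flanking measurements and flagged `interpolated`; longer gaps
stay missing and are excluded pairwise downstream. The glucose rate of
change is the backward first difference in mg/dL·min⁻¹, stamped at the later
point (a causal convention; the source of the convention is a deliberate
package choice since either stamp is defensible). Alignment matches each
glucose timestamp to the nearest envelope sample within ±1 s; unmatched
points are invalidated on *both* sides rather than physically dropped, so
the grid stays regular and temporal-shift arithmetic stays exact while all
correlations exclude invalid samples pairwise.

## Powerband envelopes

The preprocessing chain is notch filters at 60/120/180 Hz (zero-phase IIR,
Q = 30), Laplacian re-referencing along each shaft (interior contact minus
the mean of its two neighbors; shaft ends fall back to a bipolar
derivation), a zero-phase Butterworth bandpass per band (delta 1–4, theta
4–8, alpha 8–12, beta 15–25, gamma 25–70 Hz at design order 4; HFA
70–170 Hz at design order 8), the magnitude of the analytic (Hilbert)
signal, and non-overlapping 60-s boxcar means. The stated order is the
design order of the bandpass; forward–backward filtering doubles the
effective order and cancels group delay, which matters because the analysis
studies lags of hours and must not inherit filter delays. Smoothing windows
tile rather than slide, so each envelope sample is the mean of one minute
of recording; its timestamp is the window center, which by construction
falls on the 1-min grid of the recording clock. The first and last windows
are dropped as filter-transient guards. White-matter and excluded contacts
are removed before analysis.

## Lag-resolved coupling

The cross-correlogram is `r(ℓ) = corr(x(t + ℓ), y(t))` on the common 5-min
grid: negative lags mean the neural series leads. Implementation computes
all per-lag pairwise-complete Pearson correlations exactly via six
cross-correlations of masked arrays (FFT when profitable), which a naive
shifted-loop oracle reproduces to 1e−12 in the test suite. The "rectified"
best lag maximizes |r| within ±12 h (ties break toward zero lag) and the
signed correlation there is reported.

Significance uses a block permutation: the glucose series is cut into
contiguous 30-min blocks whose order is shuffled uniformly (identity
excluded), the correlogram is recomputed per draw, and the p-value of the
observed max-|r| uses the permutation distribution of max-|r| across lags —
a max-statistic correction that is stricter than testing the best lag
against a per-lag null (a per-lag variant is exposed but not default).
The estimator is (1 + #{null ≥ observed}) / (n_perm + 1), so p ∈ (0, 1].

**Calibration boundary.** The block null is exact when the 30-min blocks are
exchangeable. Measured on independent AR(1) pairs (n = 1500, α = 0.05,
200 permutations): white noise 0.048; ρ = 0.2 per 5-min step ≈ 0.06;
ρ = 0.4 ≈ 0.10; ρ = 0.5 ≈ 0.11; ρ = 0.7 ≈ 0.145. The test is therefore
progressively anti-conservative as the noise decorrelation time approaches
the block length, because permuted arrangements lose cross-boundary
correlation that the observed arrangement has. Significance calls on series
whose noise memory is a substantial fraction of 30 min should be read with
this in mind; the calibration test runs at ρ = 0.2, squarely inside the
valid regime.

State-stratified correlations first shift the neural series by the best
lag, then evaluate Pearson r over samples whose *glucose* timestamp falls
in each state (sleep, wake, pre-prandial −3→0 h, prandial 0→3 h); states
with fewer than 50 pairs are undefined. Regional roll-ups report mean ± SEM
per region, paired sleep/wake t-tests per region, and a one-way ANOVA of
lag-corrected r across regions.

## Wavelet rhythms

The continuous wavelet transform uses a Morlet mother wavelet (ω₀ = 6)
evaluated in the frequency domain with zero padding, on a log-spaced period
grid (default 0.5–48 h, 12 voices per octave, capped at one third of the
record length). Coherence smooths the scale-normalized cross- and
auto-spectra with a Gaussian of width one scale in time and a 0.6-octave
boxcar across scales (both exposed in config) and defaults to
magnitude-squared; a magnitude option exists because either reading of
"coherence" is found in practice. The cone of influence uses the Morlet
e-folding time (√2·scale) and is excluded from all averages by default —
at circadian periods a multi-day record loses roughly 1.8 days per edge,
and including the COI inflates circadian coherence.

Circadian coherence is the band-and-time mean over 24 h ± 33 % (16–32 h;
a 20–28 h narrow variant is provided because both windows are in use).
Significance reuses the 30-min block-shuffle null on the channel's own
glucose pairing. The circadian phase lag is the coherence-weighted circular
mean phase over the band, converted to hours via the 24-h band-center
period; positive values mean the neural rhythm peaks before glucose, and
values near ±12 h carry an explicit half-period wraparound warning.
Phase-vs-temporal-lag regression correlates the *phase-implied temporal
lag* (the negated phase lead, putting both variables on the temporal-lag
sign convention) with the correlogram best lag, so a common circadian drive
yields a positive R.

The circadian/ultradian decomposition is an exact complementary partition
of the Fourier spectrum: bins with periods in [18 h, 36 h] form the
circadian component, shorter periods the ultradian component, and longer
periods plus DC the residual. Because every bin belongs to exactly one
component, circadian + ultradian + residual reconstructs the input to
machine precision — the binding contract of this stage; an inverse-CWT
route would satisfy it only approximately. Ultradian coupling reruns the
full coupling analysis on the ultradian components of both series.

## Evoked potentials (CCEP)

Stimulation epochs are 2 s centered on the pulse. The 0–10 ms stimulation
artifact is blanked with a linear bridge (the magnitude window starts at
10 ms precisely so blanking cannot bias it), each epoch is baseline
corrected to its −150…+50 ms mean, and the evoked magnitude is the signed
mean of the pulse-averaged waveform over 10–150 ms. The window is
configurable because a 10–100 ms convention also exists; the two are
deliberately not reconciled. Coupled-vs-uncoupled channel groups are
compared with a two-sample t-test (≥ 5 channels per group) and magnitude
is related to per-channel coupling r by Pearson correlation.

## Glucose decoder

Features are the channels × bands envelope array flattened to 6N columns on
the 5-min grid; the target is glucose (or its derivative) at a temporal
shift, negative shift meaning neural features precede the target
(proactive decoding). Hyperglycemic values (≥ 160 mg/dL) can be clipped to
the threshold with a parallel boolean channel, so the model identifies
hyperglycemic periods rather than chasing values in a non-linear range.

Fitting is LASSO solved by least-angle regression. Rows are split 80/20
(random rows by default, replicating the headline protocol; a blocked
contiguous-tail split is first-class because random splits of
autocorrelated series inflate R, and every report names the mode).
Features are standardized with training-row statistics only — the penalty
is scale-sensitive across bands of different magnitudes. The α grid is 50
log-spaced values from the smallest empty-model α down four decades; 5-fold
CV on the training rows scores mean Pearson R per α using the piecewise
linearity of the LASSO path (one path per fold, interpolated at the grid),
ties break toward the sparser model, and the chosen α is refit on the full
training set and evaluated on the held-out rows.

The shift sweep reruns the full procedure per shift with fresh seeded
splits and reports mean CV R ± SEM across folds and the argmax (with a
boundary flag). Controls, all evaluated at the caller's optimal shift:
1-h block-shuffled target (alignment destroyed), a time-of-day mean
predictor built from 5-min-of-day bins over training rows (pure circadian),
and decoding of the wavelet circadian component and of the ultradian
deviation as separate targets; conditions are compared to the full model by
two-sample t-tests across folds. Bootstrap importance resamples rows with
replacement, refits at the fixed chosen α (the cost-saving alternative to
nesting CV in every trial), and flags columns selected in ≥ 99 % of trials;
a channel is significant when any of its bands is.

## Synthetic data: what it emulates and what it does not

Glucose is baseline 100 mg/dL + a 24-h cosine (amplitude 15 mg/dL, peak at
16:00) + shared ultradian sinusoids at 0.7/1.8/7.8 h (amplitudes 3/4/6
mg/dL, the observed ultradian periodicities) + meal responses (20 mg/dL
gamma-shaped bumps after 08:00/13:00/19:00 meals) + occasional smooth
hyperglycemia bumps crossing 160 mg/dL + AR(1) noise (sd 5 mg/dL, ρ = 0.7
per 5-min step — CGM noise is autocorrelated, and the permutation null
should be exercised against that). Coupled channels carry the same
circadian, ultradian and meal terms evaluated at t − L (L < 0 = neural
leads; default −2.8 h), scaled into envelope units (2 µV circadian
amplitude over a 20 µV baseline), plus white noise; a config switch gates
the neural ultradian drive to wake periods to emulate wake-dominant
ultradian coupling. Uncoupled channels and bands carry deliberately
detuned private sinusoids plus noise. Ultradian phases are fixed
constants, so the seed changes only noise; the same seed is byte-identical;
every emitted series equals the sum of its ground-truth components exactly
(non-negativity flooring is charged to the noise component). Default
duration is 6 days, inside the 5.5–9.3-day range such recordings span.

Deliberately not emulated: biophysically realistic voltage traces (the
generator emits envelopes directly; a thin raw-voltage mode multiplies
band-limited noise by a target envelope, enough to exercise the spectral
chain), sleep-stage microstructure, sensor drift and recalibration jumps,
meal-size variability, and any nonlinear neural–glucose transfer. Passing
recovery tests therefore demonstrates the estimators are correct and
calibrated under the stated signal model — not that real recordings carry
signals this clean.

Two constructions used by the acceptance tests are worth naming. The
*clean* construction disables meal/hyperglycemia events so the
circadian/ultradian covariance split is spectrally exact and the wavelet
ablation can be compared with the ground-truth split to within 10 %. The
*equal-information* construction for the circadian-only decoder control
matches the neural ensemble's circadian readout noise to the time-of-day
average's bin noise at the CV-fold level (σ_n = scale·√C·σ_g/√(0.64·days)),
so neither predictor has an information edge by design and the full model
and the circadian control are statistically indistinguishable; with
ultradian and meal content added back, the full model wins decisively
because the time-of-day average cannot represent non-24-h-periodic
structure.

## Numerical choices, degenerate inputs, known limitations

* Correlogram inputs are standardized before the FFT accumulations
  (Pearson is affine-invariant; conditioning improves). Lags with fewer
  than 100 overlapping pairs, constant series, and sub-50-sample states are
  undefined rather than guessed.
* Best-lag estimates are grid-quantized (5 min). For true lags between
  grid points and noise at half the signal sd, per-run errors of up to two
  grid steps occur in a few percent of runs (a plateau-tipping effect);
  the median error stays within one step and all runs within ±15 min.
* Wavelet inputs have interior gaps bridged linearly before the transform;
  outputs are re-masked. Coherence is clipped to [0, 1] after smoothing.
* The decomposition's hard spectral masks are exactly invertible but can
  ring near strong discontinuities; for the smooth physiological series
  analyzed here this is immaterial.
* The permutation and bootstrap routines draw from explicitly passed
  generators; the pipeline derives all stage generators from one master
  seed, recorded with config hash and output checksums in the run manifest.
* Cross-subject transfer, IED detection, automated sleep staging,
  electrode localization, and causal claims are out of scope; state labels
  and optional IED-rate series enter only as inputs.
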