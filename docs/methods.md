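# Methods

This note documents the models, estimators and numerical choices behind
`cogload`, and what the synthetic-data generator does and does not emulate.

## The measurement problem

During a demanding visuomotor task (the motivating setting is laparoscopic
surgery training) an operator's cognitive load is traditionally indexed by
subjective report (NASA-TLX) and by secondary-task performance (reaction
time and non-response rate to randomly timed beeps answered with a pedal).
Physiological correlates — heart rate (HR), heart rate variability (HRV)
and blink rate (BR) — promise a less intrusive, continuous readout.  The
package implements the full chain from raw-signal extraction of those three
variables to their statistical evaluation as predictors of the traditional
measures.

## Signal models and extraction

### Cardiac pulse in fNIRS

Continuous-wave fNIRS sampled at 10 Hz carries the cardiac pulsation in the
oxy-hemoglobin signal.  The chain is:

1. **Modified Beer–Lambert inversion.**  Per optode pair, optical-density
   changes at 760 and 850 nm form a 2×2 linear system in
   (Δ[HbO₂], Δ[HbR]) with molar extinction coefficients, source–detector
   distance (25 mm default) and a differential path-length factor (6.0).
   Solved exactly per sample; Δ[HbR] is retained internally but unused.
2. **Band-pass 0.5–2 Hz**, zero-phase Butterworth order 4 (applied
   forward–backward), then channel averaging.  The band admits plausible
   heart rates (30–120 bpm) and rejects Mayer waves and drift.
3. **Beat periods from zero crossings.**  Crossing times are refined by
   linear interpolation between bracketing samples; successive crossings
   alternate direction, so the interval between every other crossing spans
   one cycle.  Periods outside a [0.3, 2.0] s plausibility gate are
   discarded (the gate mirrors the filter band and guards against noise
   crossings).
4. **Instantaneous HR** = 60/period at beat midpoints, linearly
   interpolated onto the original 10 Hz grid, constant-extrapolated at the
   edges (a convention; the first/last beat's rate is the best available
   estimate there).

### Spectral HRV statistic

HRV is the high-frequency share of HR spectral power,

    HRV = HF / (HF + LF),   LF: 0.01–0.15 Hz,   HF: 0.15–0.8 Hz,

a dimensionless index in [0, 1] of how strongly respiration (respiratory
sinus arrhythmia, RSA) modulates the heart rate.  Band powers come from a
Hann-tapered periodogram of the detrended HR segment, integrated bin-wise
over each band (Welch averaging selectable).  Bins below the segment's
frequency resolution are excluded: a 30 s window cannot attribute power
below 1/30 Hz, so the effective LF band of windowed time courses starts
there.  Segments shorter than 10 s are rejected (HF unresolvable).  Episode
features use the whole episode as one segment; time courses use a 30 s
window stepped at 1 s.

The statistic needs LF-band power to discriminate anything: if HR contained
only respiratory modulation, HF/(HF+LF) would saturate at 1 for any RSA
depth.  Physiological HR also carries Mayer-wave (~0.1 Hz, blood-pressure
feedback) modulation, which anchors the LF band; the generator includes it
(see below).

### Blinks in EEG

Endogenous blinks (resting norm ≈ 14/min) are recovered from 19-channel EEG
via the standard artifact-isolation route:

1. per-episode baseline correction (whole-epoch mean);
2. excision of 1 s fragments in which any channel exceeds ±200 µV, and
   rejection of channels with sample kurtosis > 5;
3. zero-phase Hamming windowed-sinc FIR band-pass 0.16–40 Hz (kernel length
   from the low transition width, capped by record length with the kernel
   re-zeroed at DC), then decimation to 200 Hz (the 40 Hz cut-off
   anti-aliases);
4. ICA (FastICA backend behind an algorithm-agnostic contract: any
   full-rank unmixing whose sources reconstruct the data);
5. blink-component selection by **frontal dominance** (≥ 60 % of absolute
   topography weight on Fp1/Fp2/F7/F3/Fz/F4/F8) **and** source kurtosis
   (≥ 5).  This is a deliberately simple two-feature stand-in for full
   artifact classifiers (spatial-average-difference features, EM
   thresholds, eye-movement classes): with synthetic ground truth the
   two features suffice to validate the blink-rate pathway, which is the
   quantity of interest.  An empty selection is a valid outcome and marks
   BR undefined.
6. peak detection on the polarity-aligned (skew-positive), 100 ms-smoothed
   source, threshold median + 8·MAD, minimum separation 0.2 s.  The
   smoothing matches the blink timescale; the multiplier sits above the
   expected maximum of smoothed unit-variance background over multi-minute
   records (≈ 7 MAD) while blink deflections land an order of magnitude
   higher.  A 4-MAD threshold — a common first guess — fires on background
   maxima roughly ten times per minute at 200 Hz and was rejected on
   measurement.

Blink rate is events per minute of **effective** episode duration (excised
fragments subtracted).  Event times are mapped through the excision record
back to session time, so no event can fall inside a removed fragment.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth for every stage.

**Latent state.**  Two per-episode latents drive everything:

* **arousal** *a* — autonomic effort/stress; raises HR (+8 bpm per unit),
  suppresses RSA depth (−0.03 per unit), raises NASA-TLX, shortens beep
  reaction times (−0.70 on log RT) and reduces misses and handling errors;
* **visual engagement** *e* — attention captured by the primary task;
  suppresses blinks (−7.5/min per unit), lengthens beep reaction times
  (+0.45 on log RT) and raises the miss probability.

The coupling strengths are calibrated so the expected correlation sign
pattern (HR and BR negative with reaction time, HRV positive) is a robust
property of a 31-subject cohort: because the 93 pooled task rows come from
only 31 subjects, cohort-level correlations carry an sd of ≈ 0.11–0.13, and
weaker couplings would leave the sign structure at the mercy of sampling.
The resulting cohort-mean correlations (≈ −0.29 for HR, +0.43 for HRV,
−0.32 for BR against reaction time) are of the magnitude order reported for
comparable human dual-task data; no claim of magnitude fidelity is made.

Rest episodes sit at zero on both axes; the baseline (secondary task alone)
is mildly arousing but visually idle; task episodes load both, with
repetition lowering them and subject aptitude lowering arousal.  A single
latent cannot reproduce the observed association pattern — HR and BR
cannot both anti-correlate with reaction time if one variable drives all
three — which is why the generator is two-dimensional.

**Cardiac ground truth.**  Per episode,
`hr(t) = base·(1 + d·sin(2π·f_resp·t)) + A_LF·sin(2π·0.1·t) + drift`, with
per-subject base HR ~ N(70, 8) truncated to [45, 100] bpm, resting RSA
depth d ~ N(0.05, 0.015) truncated to [0.01, 0.12], respiration at 0.3 Hz,
Mayer-wave amplitude 1 bpm, and a smoothed random-walk drift (1 bpm sd).
Respiratory and Mayer phases continue across episode boundaries.
Per-subject resting blink rate ~ N(14, 3.5) truncated to [4, 30] per
minute, reflecting the large between-subject spread of spontaneous blink
rates.

**fNIRS forward model.**  The HbO₂ pulse is a 1 µM sinusoid whose phase is
the integral of hr/60; Δ[HbR] is −0.25 of it.  Channels share the cardiac
phase up to ±0.25 rad jitter — pulse arrival at neighbouring prefrontal
optodes is near-synchronous, and fully random phases would cancel under
channel averaging.  Mayer-wave sinusoids (0.4 µM), random-walk drift and
white noise (0.15 µM) are added per channel, then the two wavelength series
are produced by the forward Beer–Lambert mixing, making the inversion an
exact algebraic round trip at zero noise.

**EEG forward model.**  1/f-shaped background (20 µV sd) per channel plus a
rank-one blink artifact: a ~300 ms biphasic template at each blink time,
projected through a fixed frontal topography, 120 µV amplitude.  The
amplitude is within the range of frontal blink artifacts and deliberately
below the ±200 µV excision threshold; larger values make the cleaning step
selectively delete blink-containing windows, which biases any downstream
rate estimate (a real failure mode this generator can reproduce on demand
by raising `blink_amp_uV`).

**Blinks.**  Homogeneous Poisson with a 0.5 s refractory period
(inter-blink gap = refractory + exponential with compensated mean, so the
expected count stays rate·duration/60).

**Behaviour.**  Beep onsets with uniform 3–10 s gaps and 500–1000 ms
durations (the printed source values are dimensionally inconsistent —
"3,000 to 10,000 Hz" for intervals — and are read as ms/seconds);
lognormal response latencies; a response is a non-response if absent or
arriving after the next onset.  NASA-TLX dimensions are 25 + 40·a plus
noise, rounded to steps of 5 and clipped to [0, 100].  Completion time is
quadratic in arousal (Yerkes–Dodson: optimum at a = 0.8, 150 s curvature
gain, 20 s noise).  Error counts are Poisson with intensity decreasing in
arousal.

**What the generator does not emulate:** motion artifacts and optode
decoupling, ectopic beats and non-sinusoidal pulse shapes, non-stationary
respiration, eye movements and muscle EEG artifacts, learning dynamics
within an episode, or any specific magnitudes of the human data's
correlations.  Passing recovery tests therefore demonstrates the
correctness and calibration of the machinery under the stated model — not
field accuracy on human recordings.

## Prediction machinery

* **Pearson r** with two-sided t-distribution p, pairwise deletion of
  undefined rows; significance marked at p < 0.05 per cell with no
  multiplicity correction (the analysis is explicitly descriptive).
* **R_adj = √|adj R²|** from OLS on all nine features with intercept;
  adj R² = 1 − (1 − R²)(n−1)/(n−p−1); the absolute value keeps the square
  root defined when the adjustment pushes R² below zero.  Collinearity is
  handled by the pseudo-inverse solver.
* **Quadratic regression** of a target on [1, x, x²], model F-test p₂; a
  U-shape is flagged when the curvature is positive and the vertex lies
  inside the observed predictor range, and reported when additionally
  p₂ < 0.05.
* **Cascade-forward network**: two tanh hidden layers (10, 8), linear
  output, with direct connections from the input into every layer and from
  the first hidden layer into the output.  Trained by Levenberg–Marquardt
  on the sum of squared errors with an analytic per-sample Jacobian
  (~290 weights for 9 inputs): solve (JᵀJ + µI)δ = −Jᵀr, accept on SSE
  decrease (µ ← µ/10) else raise µ ×10, stop on gradient tolerance, µ
  overflow or the epoch budget.  Inputs and target are mapped to [−1, 1]
  with training-fold extremes.  The default budget of 30 epochs stops
  short of interpolating the training fold; full LM convergence on ~74
  training rows drives the training SSE to ~0 and measurably worsens
  held-out error.  Training is deterministic given the spec seed.
* **R_CV**: repeated fivefold cross-validation.  Each repeat draws a fresh
  random partition; out-of-fold predictions are assembled for every row and
  a single Pearson r of (prediction, actual) is computed; R_CV is the mean
  over repeats (sd reported).  Scaling and weights are fit on training
  folds only.  Repeats with constant predictions are excluded with a count.
  Default 100 repeats in tests and desk runs; 1000 for full runs.

Two calibration facts shape how the null behaviour is assessed.  First,
out-of-fold correlation on a *fixed* finite dataset estimates that
dataset's chance feature–target association, whose sd is ≈ 1/√n ≈ 0.10 at
n = 93 — so |R_CV| < 0.1 cannot be guaranteed on any single null draw by
any leak-free procedure; the leakage guard averages R_CV over independent
null datasets.  Second, fold-mean effects give honest CV a slightly
negative expectation; a positive mean null R_CV is the leakage signature.

## Group statistics and reporting

Paired comparisons use the Wilcoxon signed-rank test (zeros dropped, the
standard convention), unpaired ones the two-sample Kolmogorov–Smirnov
test.  Both are exact at cohort sizes.  A calibration caveat: with equal
group sizes the two-sample KS statistic lives on a coarse lattice and the
largest achievable size below 0.05 is ≈ 0.0396 at n = 31 vs 31, i.e. the
test is intrinsically conservative there; with the cohort's natural
unpaired split (15 vs 16 by first-task type) the achievable sizes are
dense and the empirical size is ≈ 0.05.  Calibration checks use the
15-vs-16 design.

Time courses are smoothed by a 10 s centred moving average (shrinking at
the edges) and summarised across subjects as mean ± sd; for task episodes
of unequal duration only fixed-length (40 s) segments aligned to episode
start and end are aggregated.  Boxplot summaries report median, quartiles
(linear interpolation of order statistics), whiskers to the most extreme
non-outlier points, and outliers under widened Tukey fences
q₃ + w·(q₃−q₁) / q₁ − w·(q₃−q₁) with w = 2.  (The lower fence is the
sign-corrected form; a printed "q₁ + w(q₃−q₁)" lower bound would exceed
the upper quartile.)  The rest-vs-task shift analysis regresses the
task-minus-rest change of a metric on its resting value: a flat slope
means a uniform shift (HR-like), a slope near −1 a collapse to a floor
(HRV-like; HRV is bounded below by ~0, so subjects with low resting HRV
have no room to fall — regression to the mean compounded by the bound).

## Problem sizes

Desk-scale defaults throughout: 31 simulated subjects per cohort (so the
pooled task table has 93 rows), 300 s task episodes, 100 CV repeats,
replicate counts of 20–100 per property check and 10,000 draws for test
calibration.  These sizes make every stage re-runnable in minutes on one
core while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The blink-component heuristic knows nothing about eye movements or
  electrode pops; on real data it would need the full artifact-classifier
  feature set it stands in for.
* Beat detection assumes a near-sinusoidal, artifact-free cardiac band;
  there is no motion-artifact correction or short-channel regression.
* The HRV statistic inherits the windowing trade-off: whole-episode
  segments resolve the LF band fully, 30 s windows only above 1/30 Hz.
* LM training scales with the square of the weight count; the
  implementation targets nets of a few hundred weights, not larger
  architectures.
* All quantitative guarantees are statements about the generator's model
  class, verified by simulation; none are claims about human data.
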