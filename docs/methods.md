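# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Signal derivation

The raw voltage is trial-segmented, in microvolts, at a nominal 32.5 kHz.
Re-referencing subtracts the mean of designated non-spiking reference
channels sample-wise.

* **LFP** — polyphase resampling (with built-in anti-alias filtering) to
  exactly 930 Hz, then a zero-phase (forward–backward) 2nd-order
  Butterworth band-pass 1–200 Hz, then per-trial 50 Hz removal.
  Resampling precedes the band-pass; the anti-alias low-pass inside the
  polyphase stage prevents the aliasing this order would otherwise
  invite. Line removal regresses each trial on the 50 Hz quadrature pair
  (closed-form least squares) and subtracts the fitted sinusoid;
  harmonics are not fitted. Samples within 150 ms of the trial edges are
  excluded from the regression because the zero-phase high-pass distorts
  them; the fitted sinusoid is still subtracted everywhere. A genuinely
  zero line component fits near-zero amplitude, so the operation is a
  safe no-op.
* **MUA envelope** — zero-phase 2nd-order Butterworth band-pass
  500 Hz–5 kHz at the native rate (upper edge capped below Nyquist when
  the rate is low), absolute value, resample to 930 Hz, zero-phase
  low-pass < 200 Hz. The chain is linear in the input amplitude up to
  rectification, so scaling the raw trace scales the envelope.
* **Spike times** — threshold k·σ̂ on the band-passed trace with
  σ̂ = median(|v|)/0.6745 (the standard unbiased MAD estimator for
  Gaussian noise; a `mad_convention="multiply"` switch provides the
  multiplicative reading). k defaults to 3.5, with 4.0 used for
  size-tuning sessions. The event time is the absolute-voltage maximum
  within 0.75 ms after the crossing; crossings within a 1.5 ms dead time
  of the previous accepted crossing are ignored, and positive and
  negative crossings share one dead time.
* **SDF** — spike times binned at 1.1 ms and convolved with a Gaussian
  kernel (σ = 3.2 ms) truncated to 21 bins (23.1 ms — the closest odd bin
  count to a 22.6 ms support) and renormalized to unit sum, so a single
  spike integrates to exactly one spike.

Normalization schemes subtract the grand pre-stimulus (−200–0 ms)
baseline, then divide by, depending on the analysis: the best grid
location's 50–300 ms mean (`rf_map`), the condition-mean peak in
30–150 ms across conditions (`max_across_conditions`), the center-only
condition's peak (`center_only_max`), or the grand-mean peak
(`grand_mean_max`). The denominator is recorded in the output.

## Receptive fields

Response maps average windowed activity (MUA 50–300 ms; gamma power
100–250 ms) per grid location and divide by the maximum across locations.
The 2-D elliptical Gaussian has no amplitude or offset parameter (the map
is already max-normalized); an optional amplitude term exists but is off
by default. Fitting is Nelder-Mead on the residual sum of squares with
widths optimized on a log scale, initialized from the map argmax and
second moments with 8 jittered restarts (the objective is multimodal in
θ). Degenerate all-zero maps set `converged=False` rather than raising.
RF size is the FWHM averaged over the fitted x/y axes, not over principal
axes. Latency uses per-sample Welch t-tests (robust to unequal variances)
between the ~10% nearest and ~10% farthest grid locations (count rounded
to nearest, 12 on an 11×11 grid); the latency is the first significant
sample followed by `run_length` (10) consecutive significant samples, so
increasing `run_length` can only delay it.

## Tuning

1−CircVar uses doubled angles for orientation and plain angles for
direction. Baseline-subtracted responses are clipped at zero first — the
statistic assumes nonnegative weights, and negative weights could push
the ratio above 1. The bootstrap null resamples trial responses with
replacement onto the original angle labels and recomputes the statistic
on condition means; p = (1 + #{null ≥ observed})/(1 + n_boot), which is
slightly conservative and never exactly zero. Under an untuned null the
p-distribution is uniform to KS accuracy and the type-I error at α = 0.05
sits in [0.03, 0.07] over 500 sessions (verified in the acceptance
suite).

Curve fits operate on condition means, equally weighted, of the 0–0.5 s
window response. The Naka-Rushton exponent is bounded to [0.5, 6] to
exclude step-like degenerate fits; C50 to [0.1, 500]% contrast. The
ratio-of-Gaussians fit bounds all four parameters positive; the optimal
size is the argmax of the fitted curve on a 2000-point grid over [0, max
tested size], and SI = (Rmax − R(max size))/Rmax, so monotonically rising
data legitimately give SI ≈ 0. All fits flag rather than raise
non-convergence.

## Spectra

Power spectra are Hann-tapered, one-sided, scaled so that the summed
power equals the windowed signal energy (Parseval). Relative change is
the bin-wise stimulus/baseline power ratio (windows 0.15–0.45 s vs −0.3–0 s
by default); when the two windows differ in length the baseline spectrum
is linearly interpolated onto the stimulus grid. The gamma peak is fit
with the density-normalized Gaussian G·e^{−(f−μ)²/2σ²}/(√(2π)σ) + b over
30–100 Hz by Nelder-Mead (σ on a log scale, two starting centers); the
reported peak height is G/(√(2π)σ), and `no_peak` is set when the height
is below 5% of the offset, the amplitude is nonpositive, or μ pins to a
range edge — "no detectable peak" has no standard quantitative
definition, so this criterion is the package's own. An
amplitude-spectrum variant (√power before the ratio) is available by
flag.

Gamma response maps average spectra across a location's trials *before*
taking the stimulus/baseline ratio: single-trial power ratios are ratios
of small-dof χ² variates with heavy tails that destabilize the Gaussian
fit. The mapped quantity is the band-mean (40–120 Hz) fractional increase
(ratio − 1), so locations without induced gamma sit near zero as the
offset-free Gaussian model assumes. Because induced power grows roughly
as the square of the underlying response gain, the gamma RF is
systematically narrower than the MUA RF (FWHM smaller by about √2 for a
Gaussian gain profile) — the pipeline reproduces this dissociation on
synthetic data.

## Context and attention

OTSS is the Cross − Iso90 mean difference, FGM is Iso90 − Iso; both are
summarized in early (50–100 ms) and late (100–500 ms) windows with Welch
t-tests on trial-level window means. Latency is the rising half-maximum
μ − σ√(2 ln 2) of a Gaussian bump (amplitude, center, width, offset) fit
to the modulation time course over 0–500 ms. Three numerical safeguards
matter here, all motivated by plateau-like sustained modulations:

* the time course is smoothed with a 21.5 ms boxcar before the latency
  fit only — window statistics always use unsmoothed data;
* amplitude is bounded to 1.5× the data range, σ to ≤ 400 ms, and the
  offset to ±15% of the range around the mean of the first 10% of the fit
  window, where a stimulus-locked modulation is structurally absent.
  Without the offset anchor, the flank of an enormous out-of-window
  Gaussian fits any plateau and yields meaningless (often negative)
  latencies;
* solutions with σ pinned at its bound are discarded, and a fit must
  explain ≥ 20% of the variance — pure noise therefore returns an absent
  value rather than a number.

On a noiseless Gaussian bump the estimator is exact. On ramp-plus-decay
modulations it estimates the shape's own half-rise time with a residual
bias of order ±20–30 ms when the modulation is strongly sustained; the
generator exposes `true_modulation_halfrise` so recovery is always judged
against the programmed shape, not the onset parameter.

Attentional modulation pools the near and far distractor conditions,
tests target vs distractor in 0–150 ms and 200–500 ms windows, and
reports the near-vs-far comparison separately. Pooling modulation time
courses across sessions (or electrodes) before the latency fit is the
caller's decision; the acceptance script pools three simulated sessions.

## Eye movements

Velocity is a central difference over ±2 samples of 5-sample
boxcar-smoothed position (1 kHz traces) — unsmoothed differentiation
would cross 10°/s on quantization noise alone. Microsaccades are maximal
runs of speed > 10°/s lasting ≥ 10 ms; runs separated by < 5 ms merge
into one event. Fixation filtering keeps trials whose gaze stays within a
configurable radius (2° online criterion, 1° offline). Group comparisons
of trial-mean position and speed use Mann-Whitney U tests.

## The synthetic generator

Each trial sums: 1/f background (unit-variance by analytic scaling — see
below) with a spectral corner at 300 Hz above which power falls as 1/f³;
broadband white noise that sets the spike-band floor; a 10 Hz alpha
oscillation confined to the pre-stimulus epoch; a 50 Hz line sinusoid
with per-trial phase; stimulus-locked gamma (a sinusoid with
per-condition amplitude and frequency for gratings; a 40–120 Hz noise
burst for checkerboard flashes, whose induced gamma is broad-band); and
biphasic ~1 ms spike waveforms from a 1 ms-binned Poisson process.

Two generator details are deliberate:

* the 1/f noise is scaled by its *expected* rms, computed from the shaped
  spectrum, not by the realized per-trial std — sample-std normalization
  would let chance low-frequency power modulate the spike-band floor
  trial by trial, inflating response variance in a way real backgrounds
  do not;
* the spectral corner keeps the 1/f component out of the 500 Hz–5 kHz
  band, so the spike-band floor is the white (thermal/amplifier)
  component, as in real recordings.

Default ground truth: RF at (10°, −2.5°) with σ = 1.87° (FWHM ≈ 4.4°);
preferred orientation 171° with σ = 49° (HWHM ≈ 58°); baseline 15 and
peak 150 spikes/s (multi-unit aggregates of many neurons fire far above
single-unit rates; these values give the bootstrap and window tests
realistic statistical power at realistic trial counts); C50 = 7.3%,
exponent 2; ROG (Ge, Gi, We, Wi) = (2, 1, 2°, 6°), whose optimal size is
3.02° and SI 0.31; gamma base frequency 55 Hz with amplitude and
frequency following the tuning gain (untuned conditions keep ~30%
amplitude and −2 Hz); response latency 57 ms. The driven rate adapts from
its onset transient to a 0.5 sustained fraction with τ = 100 ms, which is
what makes peak-window normalization meaningful. Contextual offsets are
(offset, onset, rise, sustained) entries: iso-surround suppression −40
spikes/s from 55 ms with a 20 ms rise; figure-ground enhancement +40 from
90 ms with an 80 ms rise; both decay toward 0.15 sustained so the late
Iso90 response matches Cross (late OTSS ≈ 0, the double dissociation).
Attentional enhancement is +20 spikes/s from 200 ms, 80 ms rise, nearly
sustained (0.9). Programmed half-rises: OTSS 67 ms, FGM 109 ms.

Randomness: trial k uses child stream k of `SeedSequence(session_seed)`,
the eye trace uses the last child; identical seed and config give
bit-identical datasets.

Trial counts are generator knobs, not claims: grid mapping defaults to 5
repeats per location (605 trials), tuning sessions to 10 repeats per
condition, context to 80 trials per condition, curve tracing to 45 per
condition (135 total). Eye traces are an Ornstein-Uhlenbeck drift
(σ = 0.08°, τ = 1 s) whose velocity stays far below the 10°/s threshold,
plus scheduled constant-velocity microsaccade ramps.

## Problem sizes and verification scope

Tests and the acceptance script simulate at 12.5 kHz — comfortably above
the 2 × 5 kHz spike-band requirement and spectrally equivalent for every
analysis band — and use the default trial counts above; the full suite
runs in well under a minute and the acceptance script in a few minutes on
one CPU. Parameter-recovery tolerances (RF center 0.5°, FWHM 15%,
preferred orientation ±10°, C50 15%, optimal size 20%, gamma peak 1.5
bins) were calibrated by Monte-Carlo over dozens of seeds before being
frozen; C50 and optimal-size recoveries are reported as medians over a
few independent sessions because single-session estimates have occasional
heavy-tailed errors.

What passing tests do **not** show: the generator has no biophysical
neuron model, no realistic stimulus rendering, no spike-waveform
diversity or electrode drift, no correlated trial-to-trial population
state, and Poisson (not over-dispersed) spiking. Recovery results
therefore demonstrate the correctness of the analysis chain under the
stated generative model, not performance guarantees on patient data.
Quantities measured from real recordings (RF sizes of specific
electrodes, their latencies, C50s, SIs, modulation latencies) can only be
reproduced from those recordings themselves, which this package's
pipeline accepts through the same entry points.
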