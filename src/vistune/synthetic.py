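"""Ground-truth simulator for microwire sessions in early visual cortex.

Each simulated trial is the sum of

* 1/f ("pink") background noise plus a 10 Hz alpha oscillation restricted to
  the pre-stimulus epoch (stimuli suppress alpha),
* a 50 Hz line-noise sinusoid with a per-trial phase,
* broadband white noise that dominates the 500 Hz - 5 kHz spike band,
* a stimulus-locked narrow-band gamma sinusoid whose amplitude and frequency
  depend on the trial's condition,
* a train of biphasic spike waveforms from an inhomogeneous Poisson process
  whose rate follows the ground-truth tuning model for the trial's stimulus,
  delayed by the true response latency.

All randomness flows from a single session seed: trial ``k`` uses the child
stream ``SeedSequence(seed).spawn(n_trials + 1)[k]`` and the eye trace uses
the last child, so datasets are bit-reproducible and individual trials are
independent of trial order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .types import EyeTrace, GroundTruth, SyntheticDataset, WidebandRecording

EXPERIMENTS = ("rf", "orientation", "contrast", "size", "context", "tracing")

STIMULUS_COLUMNS = [
    "trial", "experiment", "grid_x", "grid_y", "direction", "orientation",
    "spatial_freq", "contrast", "diameter", "phase", "condition", "correct",
]


@dataclass
class NoiseConfig:
    """Amplitudes and timing of the simulated background signal.

    Voltages are microvolts.  ``spike_snr`` scales the spike-waveform peak
    relative to the background RMS inside the 500 Hz - 5 kHz band, so the
    waveform survives the band-pass + robust-threshold detection stage.
    """

    sampling_rate: float = 32500.0
    pre_ms: float = 300.0
    stim_ms: float = 500.0
    tail_ms: float = 200.0
    pink_rms: float = 20.0        # 1/f background
    white_rms: float = 4.0        # broadband; sets the spike-band floor
    alpha_amp: float = 12.0       # pre-stimulus 10 Hz oscillation
    alpha_freq: float = 10.0
    line_amp: float = 5.0
    line_freq: float = 50.0
    gamma_base_amp: float = 10.0  # microvolts at relative gamma amplitude 1
    spike_snr: float = 12.0
    gamma_ramp_ms: float = 10.0
    flash_gamma_band: tuple = (40.0, 120.0)

    @property
    def trial_ms(self) -> float:
        return self.pre_ms + self.stim_ms + self.tail_ms

    def spike_band_rms(self) -> float:
        """RMS of the white background inside 500 Hz - 5 kHz (analytic)."""
        nyq = self.sampling_rate / 2.0
        hi = min(5000.0, nyq)
        return self.white_rms * np.sqrt(max(hi - 500.0, 0.0) / nyq)


# ---------------------------------------------------------------------------
# stimulus designs


def _empty_table(n: int, experiment: str) -> pd.DataFrame:
    df = pd.DataFrame({c: np.full(n, np.nan) for c in STIMULUS_COLUMNS})
    df["trial"] = np.arange(n)
    df["experiment"] = experiment
    df["condition"] = ""
    df["correct"] = True
    return df


def rf_grid_design(rows: int = 11, cols: int = 11, spacing: float = 1.0,
                   repeats: int = 5, center=(10.0, -2.5)) -> pd.DataFrame:
    """Checkerboard-flash mapping grid: ``rows x cols`` locations, repeated."""
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    xs = (np.arange(cols) - (cols - 1) / 2.0) * spacing + center[0]
    ys = (np.arange(rows) - (rows - 1) / 2.0) * spacing + center[1]
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = np.tile(gx.ravel(), repeats), np.tile(gy.ravel(), repeats)
    df = _empty_table(gx.size, "rf")
    df["grid_x"], df["grid_y"] = gx, gy
    df["condition"] = [f"({x:g},{y:g})" for x, y in zip(gx, gy)]
    return df


def orientation_design(repeats: int = 10, n_directions: int = 24,
                       contrast: float = 80.0, diameter: float = 10.0,
                       spatial_freq: float = 1.0) -> pd.DataFrame:
    """Drifting gratings at ``n_directions`` directions (default 0-345 deg, 15 deg steps)."""
    dirs = np.tile(np.arange(n_directions) * 360.0 / n_directions, repeats)
    df = _empty_table(dirs.size, "orientation")
    df["direction"] = dirs
    df["orientation"] = dirs % 180.0
    df["contrast"], df["diameter"], df["spatial_freq"] = contrast, diameter, spatial_freq
    df["condition"] = [f"{d:g}" for d in dirs]
    return df


def contrast_design(repeats: int = 10,
                    contrasts=(1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 100.0),
                    orientation: float = 45.0) -> pd.DataFrame:
    cs = np.tile(np.asarray(contrasts, dtype=float), repeats)
    df = _empty_table(cs.size, "contrast")
    df["contrast"] = cs
    df["direction"], df["orientation"] = orientation, orientation % 180.0
    df["diameter"], df["spatial_freq"] = 10.0, 1.0
    df["condition"] = [f"{c:g}" for c in cs]
    return df


def size_design(repeats: int = 10,
                sizes=(0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0),
                orientation: float = 45.0) -> pd.DataFrame:
    ss = np.tile(np.asarray(sizes, dtype=float), repeats)
    df = _empty_table(ss.size, "size")
    df["diameter"] = ss
    df["direction"], df["orientation"] = orientation, orientation % 180.0
    df["contrast"], df["spatial_freq"] = 80.0, 1.0
    df["condition"] = [f"{s:g}" for s in ss]
    return df


def context_design(repeats: int = 40, diameter: float = 6.0,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Stationary center gratings (orientations 60/150 deg, balanced) in the four
    surround conditions CenterOnly / Iso / Iso90 / Cross."""
    conds = ["CenterOnly", "Iso", "Iso90", "Cross"]
    cond, ori = [], []
    for c in conds:
        for o in (60.0, 150.0):
            cond += [c] * (repeats // 2)
            ori += [o] * (repeats // 2)
    df = _empty_table(len(cond), "context")
    df["condition"], df["orientation"] = cond, ori
    df["diameter"], df["contrast"], df["spatial_freq"] = diameter, 80.0, 1.0
    if rng is not None:
        df["phase"] = rng.uniform(-np.pi, np.pi, len(df))
    return df


def tracing_design(repeats: int = 45) -> pd.DataFrame:
    """Curve-tracing task: RF on the target curve or a near/far distractor."""
    conds = ["Target", "DistractorNear", "DistractorFar"]
    cond = np.repeat(conds, repeats)
    df = _empty_table(cond.size, "tracing")
    df["condition"] = cond
    return df


def make_design(experiment: str, **kwargs) -> pd.DataFrame:
    builders = {
        "rf": rf_grid_design, "orientation": orientation_design,
        "contrast": contrast_design, "size": size_design,
        "context": context_design, "tracing": tracing_design,
    }
    if experiment not in builders:
        raise ValueError(f"unknown experiment type: {experiment!r}")
    return builders[experiment](**kwargs)


# ---------------------------------------------------------------------------
# tuning-gain models (ground truth)


def ang_ori(x):
    """Wrap an orientation difference (deg) to [0, 90]."""
    x = np.asarray(x, dtype=float)
    return np.minimum(np.minimum(np.abs(x), np.abs(x - 180.0)), np.abs(x + 180.0))


def rog_response(x, ge, gi, we, wi):
    """Ratio-of-Gaussians size-tuning curve R(x) = Ge erf(x/We)^2 / (1 + Gi erf(x/Wi)^2)."""
    x = np.asarray(x, dtype=float)
    return ge * erf(x / we) ** 2 / (1.0 + gi * erf(x / wi) ** 2)


def naka_rushton(x, b, n, c50):
    x = np.asarray(x, dtype=float)
    return b * x ** n / (c50 ** n + x ** n)


def tuning_gain(truth: GroundTruth, row: pd.Series) -> float:
    """Normalized stimulus drive in [0, 1] for one trial's parameters."""
    exp = row["experiment"]
    if exp == "rf":
        dx = row["grid_x"] - truth.rf_center[0]
        dy = row["grid_y"] - truth.rf_center[1]
        return float(np.exp(-(dx ** 2 + dy ** 2) / (2.0 * truth.rf_sigma ** 2)))
    if exp == "orientation":
        d = ang_ori(row["orientation"] - truth.pref_orientation)
        return float(np.exp(-d ** 2 / (2.0 * truth.tuning_width_sigma ** 2)))
    if exp == "contrast":
        nr = naka_rushton(row["contrast"], 1.0, truth.naka_exponent, truth.c50_true)
        nr100 = naka_rushton(100.0, 1.0, truth.naka_exponent, truth.c50_true)
        return float(nr / nr100)
    if exp == "size":
        ge, gi, we, wi = truth.rog_params
        grid = np.linspace(1e-3, 12.0, 600)
        return float(rog_response(row["diameter"], ge, gi, we, wi)
                     / rog_response(grid, ge, gi, we, wi).max())
    if exp in ("context", "tracing"):
        return 1.0  # full drive in the RF; condition effects are additive offsets
    raise ValueError(f"unknown experiment type: {exp!r}")


# Modulation entries are (offset spikes/s, onset ms[, rise ms[, sustained]]).
# Iso-oriented surrounds suppress quickly from ~55 ms (orientation-tuned
# surround suppression); figure-ground enhancement of the segregated center
# is a feedback effect that develops slowly from ~98 ms, peaks, partially
# decays, and cancels the suppression so the late Iso90 response matches
# Cross.
DEFAULT_CONTEXT_MODULATION = {
    "CenterOnly": [],
    "Iso": [(-40.0, 55.0, 20.0, 0.15)],
    "Iso90": [(-40.0, 55.0, 20.0, 0.15), (40.0, 90.0, 40.0, 0.15)],
    "Cross": [],
}

# object-based attention: ~15% enhancement of the target-curve response,
# spreading gradually from 200 ms onward and then sustained
DEFAULT_TRACING_MODULATION = {
    "Target": [(20.0, 200.0, 80.0, 0.9)],
    "DistractorNear": [],
    "DistractorFar": [],
}


def _modulation_for(truth: GroundTruth, row: pd.Series) -> list:
    if truth.modulation is not None:
        return truth.modulation.get(row["condition"], [])
    if row["experiment"] == "context":
        return DEFAULT_CONTEXT_MODULATION.get(row["condition"], [])
    if row["experiment"] == "tracing":
        return DEFAULT_TRACING_MODULATION.get(row["condition"], [])
    return []


def rate_profile(truth: GroundTruth, row: pd.Series, t_ms: np.ndarray,
                 stim_ms: float) -> np.ndarray:
    """Programmed firing rate (spikes/s) on the time grid ``t_ms``."""
    lat = truth.response_latency_true
    rate = np.full(t_ms.shape, truth.baseline_rate, dtype=float)
    drive = (t_ms >= lat) & (t_ms < stim_ms + lat)
    # onset transient decaying to a sustained level (cortical adaptation);
    # additive modulations ride on the same adapting population response
    adapt = np.ones_like(t_ms)
    u = np.clip(t_ms - lat, 0.0, None)
    adapt = truth.sustained_fraction + (1.0 - truth.sustained_fraction) * \
        np.exp(-u / truth.adapt_tau_ms)
    rate[drive] += ((truth.peak_rate - truth.baseline_rate)
                    * tuning_gain(truth, row) * adapt[drive])
    for entry in _modulation_for(truth, row):
        offset, onset = entry[0], entry[1]
        rise = entry[2] if len(entry) > 2 else truth.mod_rise_ms
        sustained = entry[3] if len(entry) > 3 else truth.mod_sustained
        # onsets are absolute post-stimulus times; nothing modulates before
        # the visual response itself arrives
        o = max(onset, lat)
        m = (t_ms >= o) & (t_ms < stim_ms + lat)
        v = np.clip(t_ms - o, 0.0, None)
        ramp = np.clip(v / max(rise, 1e-9), 0.0, 1.0)
        decay = sustained + (1.0 - sustained) * np.exp(-v / truth.mod_tau_ms)
        rate[m] += offset * (ramp * decay)[m]
    return np.clip(rate, 0.0, None)


def true_modulation_timecourse(truth: GroundTruth, experiment: str,
                               cond_a: str, cond_b: str,
                               stim_ms: float = 500.0, dt_ms: float = 1.0):
    """Noiseless programmed rate difference between two conditions.

    Returns ``(t_ms, rate_a - rate_b)`` — the ground-truth counterpart of a
    measured modulation time course.
    """
    t = np.arange(0.0, stim_ms, dt_ms)
    rows = {c: pd.Series({"experiment": experiment, "condition": c})
            for c in (cond_a, cond_b)}
    diff = rate_profile(truth, rows[cond_a], t, stim_ms) - \
        rate_profile(truth, rows[cond_b], t, stim_ms)
    return t, diff


def true_modulation_halfrise(truth: GroundTruth, experiment: str,
                             cond_a: str, cond_b: str,
                             stim_ms: float = 500.0) -> float:
    """Time (ms) at which the programmed modulation first reaches half its peak."""
    t, diff = true_modulation_timecourse(truth, experiment, cond_a, cond_b, stim_ms)
    peak = diff.max()
    if peak <= 0:
        raise ValueError("programmed modulation has no positive peak")
    return float(t[np.argmax(diff >= 0.5 * peak)])


def _gamma_for(truth: GroundTruth, row: pd.Series) -> tuple[float, float]:
    """(relative amplitude, frequency Hz) of the trial's gamma component."""
    cond = row["condition"]
    if truth.gamma_amp_per_condition is not None:
        amp = truth.gamma_amp_per_condition.get(cond, 0.0)
    else:
        gain = tuning_gain(truth, row)
        amp = 0.3 + 0.7 * gain if row["experiment"] != "rf" else gain
    if truth.gamma_freq_per_condition is not None:
        freq = truth.gamma_freq_per_condition.get(cond, truth.gamma_base_freq)
    else:
        gain = tuning_gain(truth, row)
        freq = truth.gamma_base_freq - 2.0 + 4.0 * gain
    return float(amp), float(freq)


# ---------------------------------------------------------------------------
# signal components


def pink_noise(rng: np.random.Generator, n: int, fs: float = 1.0,
               corner_hz: float = 300.0) -> np.ndarray:
    """1/f-power background noise with *expected* unit variance.

    Power falls as 1/f up to ``corner_hz`` and as 1/f^3 above it: the slow
    component models aggregate synaptic activity while the corner keeps the
    background out of the 500 Hz - 5 kHz spike band, where the floor is set
    by the (white) thermal/amplifier noise instead.

    The scale is derived analytically from the shaped spectrum rather than
    from the realized trial variance: normalizing by the sample std would
    let chance low-frequency power modulate the high-frequency floor from
    trial to trial, which real background activity does not do.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1]
    shape = f ** -0.5
    hi = f > corner_hz
    shape[hi] *= (corner_hz / f[hi])
    spec *= shape
    # E[sum x^2] = sum_k c_k E|X_k|^2 / n with E|X_k|^2 = n * shape_k^2
    c = np.full(f.size, 2.0)
    c[0] = 1.0
    if n % 2 == 0:
        c[-1] = 1.0
    expected_rms = np.sqrt((c * shape ** 2).sum() / n)
    return np.fft.irfft(spec, n) / expected_rms


def spike_template(fs: float, snr_amp: float) -> np.ndarray:
    """Biphasic ~1 ms waveform (negative-first) with peak amplitude ``snr_amp``."""
    ns = max(int(round(fs * 1e-3)), 4)
    ph = np.linspace(0.0, 2.0 * np.pi, ns, endpoint=False)
    w = -np.sin(ph) * np.hanning(ns)
    return w / np.abs(w).max() * snr_amp


def _raised_edges(mask: np.ndarray, ramp_n: int) -> np.ndarray:
    """Soft 0->1 envelope from a boolean mask using cosine ramps."""
    env = mask.astype(float)
    if ramp_n > 1:
        k = np.hanning(2 * ramp_n + 1)
        env = np.convolve(env, k / k.sum(), mode="same")
    return env


def _simulate_trial(truth: GroundTruth, row: pd.Series, noise: NoiseConfig,
                    rng: np.random.Generator) -> np.ndarray:
    fs = noise.sampling_rate
    n = int(round(fs * noise.trial_ms / 1000.0))
    t_ms = -noise.pre_ms + np.arange(n) * 1000.0 / fs
    t_s = t_ms / 1000.0

    x = pink_noise(rng, n, fs) * noise.pink_rms
    x += rng.standard_normal(n) * noise.white_rms
    x += noise.line_amp * np.sin(2 * np.pi * noise.line_freq * t_s
                                 + rng.uniform(0, 2 * np.pi))

    # pre-stimulus alpha, suppressed once the stimulus appears
    alpha_env = _raised_edges(t_ms < 0.0, int(round(fs * 0.05)))
    x += noise.alpha_amp * alpha_env * np.sin(
        2 * np.pi * noise.alpha_freq * t_s + rng.uniform(0, 2 * np.pi))

    # stimulus-locked gamma: narrow-band sinusoid for gratings, broad-band
    # (40-120 Hz) noise burst for the brief checkerboard flashes
    amp_rel, freq = _gamma_for(truth, row)
    if amp_rel > 0:
        gmask = (t_ms >= truth.response_latency_true) & (t_ms < noise.stim_ms)
        env = _raised_edges(gmask, int(round(fs * noise.gamma_ramp_ms / 1000.0)))
        if row["experiment"] == "rf":
            from scipy.signal import butter, sosfiltfilt
            sos = butter(4, noise.flash_gamma_band, btype="bandpass", fs=fs,
                         output="sos")
            burst = sosfiltfilt(sos, rng.standard_normal(n))
            burst /= burst.std()
            x += noise.gamma_base_amp * amp_rel * env * burst
        else:
            x += noise.gamma_base_amp * amp_rel * env * np.sin(
                2 * np.pi * freq * t_s + rng.uniform(0, 2 * np.pi))

    # inhomogeneous Poisson spikes: 1 ms binned thinning
    bin_edges_ms = np.arange(-noise.pre_ms, -noise.pre_ms + noise.trial_ms + 1e-9, 1.0)
    bin_t = bin_edges_ms[:-1]
    rate = rate_profile(truth, row, bin_t, noise.stim_ms)
    counts = rng.poisson(rate * 1e-3)
    spike_ms = np.repeat(bin_t, counts) + rng.uniform(0.0, 1.0, counts.sum())
    w = spike_template(fs, noise.spike_snr * noise.spike_band_rms())
    idx = np.round((spike_ms + noise.pre_ms) * fs / 1000.0).astype(int)
    for i in idx:
        j = min(i + w.size, n)
        x[i:j] += w[: j - i]
    return x


# ---------------------------------------------------------------------------
# public entry points


def simulate_session(truth: GroundTruth, design: pd.DataFrame,
                     noise: NoiseConfig | None = None) -> SyntheticDataset:
    """Simulate a full session for one experiment type.

    ``design`` must come from one of the design builders (one experiment
    kind per session).  Reproducible: identical (truth.seed, design, noise)
    give a bit-identical dataset.
    """
    noise = noise or NoiseConfig()
    if noise.pre_ms <= 0 or noise.stim_ms <= 0:
        raise ValueError("pre/stim durations must be positive")
    kinds = design["experiment"].unique()
    if len(kinds) != 1 or kinds[0] not in EXPERIMENTS:
        raise ValueError(f"design must cover exactly one known experiment, got {kinds}")

    n_trials = len(design)
    children = np.random.SeedSequence(truth.seed).spawn(n_trials + 1)
    trials = [_simulate_trial(truth, design.iloc[k], noise,
                              np.random.default_rng(children[k]))
              for k in range(n_trials)]
    rec = WidebandRecording(np.stack(trials)[:, None, :], noise.sampling_rate,
                            t0_offset_ms=-noise.pre_ms, channel_ids=("sim0",))
    eye = simulate_eye_trace(
        fixation_center=(0.0, 0.0), drift_sd=0.08, microsaccade_schedule=[],
        n_trials=n_trials, duration_ms=noise.trial_ms, t0_offset_ms=-noise.pre_ms,
        rng=np.random.default_rng(children[-1]))
    return SyntheticDataset(rec, design.reset_index(drop=True), eye, truth)


def simulate_rf_grid(truth: GroundTruth, grid_spec: dict | None = None,
                     noise: NoiseConfig | None = None) -> SyntheticDataset:
    """Simulate the checkerboard-flash RF mapping experiment.

    ``grid_spec`` keys: rows, cols, spacing, repeats, center.
    """
    design = rf_grid_design(**(grid_spec or {}))
    return simulate_session(truth, design, noise)


def simulate_eye_trace(fixation_center=(0.0, 0.0), drift_sd: float = 0.08,
                       microsaccade_schedule=(), n_trials: int = 1,
                       duration_ms: float = 1000.0, t0_offset_ms: float = 0.0,
                       sampling_rate: float = 1000.0,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> EyeTrace:
    """Fixational gaze traces with slow drift plus scheduled microsaccades.

    Drift is an Ornstein-Uhlenbeck walk around the fixation center whose
    velocity stays well below the 10 deg/s detection threshold.  Each
    scheduled microsaccade ``(onset_ms, amplitude_deg, duration_ms)`` is a
    constant-velocity ramp in a random direction, so its speed
    ``amplitude/duration`` exceeds threshold for essentially the stated
    duration.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_ms * sampling_rate / 1000.0))
    dt = 1.0 / sampling_rate
    for onset, amp, dur in microsaccade_schedule:
        if dur < 2 * 1000.0 * dt:
            raise ValueError("microsaccade duration must span at least 2 samples")

    xs = np.empty((n_trials, n))
    ys = np.empty((n_trials, n))
    tau = 1.0  # s; mean-reversion time of the drift
    for k in range(n_trials):
        x = np.zeros(n)
        y = np.zeros(n)
        step = drift_sd * np.sqrt(2.0 * dt / tau)
        ex = rng.standard_normal(n) * step
        ey = rng.standard_normal(n) * step
        for i in range(1, n):
            x[i] = x[i - 1] * (1.0 - dt / tau) + ex[i]
            y[i] = y[i - 1] * (1.0 - dt / tau) + ey[i]
        for onset, amp, dur in microsaccade_schedule:
            i0 = int(round((onset - t0_offset_ms) * sampling_rate / 1000.0))
            ns = int(round(dur * sampling_rate / 1000.0))
            if i0 < 0 or i0 + ns > n:
                continue
            ang = rng.uniform(0, 2 * np.pi)
            ramp = np.linspace(0.0, amp, ns)
            x[i0:i0 + ns] += ramp * np.cos(ang)
            x[i0 + ns:] += amp * np.cos(ang)
            y[i0:i0 + ns] += ramp * np.sin(ang)
            y[i0 + ns:] += amp * np.sin(ang)
        xs[k] = x + fixation_center[0]
        ys[k] = y + fixation_center[1]
    return EyeTrace(xs, ys, sampling_rate, t0_offset_ms)
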