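"""Derivation of LFP, MUA envelope, spike times and spike-density functions
from trial-segmented wideband voltage.

The chain mirrors standard microwire practice:

* LFP: polyphase resample to 930 Hz, zero-phase 2nd-order Butterworth
  band-pass 1-200 Hz, per-trial 50 Hz sine subtraction;
* MUA envelope: zero-phase band-pass 500 Hz - 5 kHz at the native rate,
  full-wave rectification (absolute value), resample to 930 Hz, zero-phase
  low-pass < 200 Hz;
* spike times (thresholded multi-unit activity): threshold at k times a
  robust deviation estimate of the band-passed trace, with a 1.5 ms dead
  time; the spike time is the absolute-voltage maximum within 0.75 ms of
  the crossing;
* spike-density function: 1.1 ms binning convolved with a truncated,
  unit-integral Gaussian kernel (sigma 3.2 ms, total length 22.6 ms).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .types import DerivedSignals, WidebandRecording, window_mask

LFP_RATE = 930.0
SDF_BIN_MS = 1.1
SDF_KERNEL_MS = 22.6
SDF_SIGMA_MS = 3.2
DEAD_TIME_MS = 1.5
PEAK_SEARCH_MS = 0.75


def _resample(x: np.ndarray, fs: float, target: float = LFP_RATE) -> np.ndarray:
    """Polyphase resampling (with built-in anti-alias filtering) along the last axis."""
    frac = Fraction(target / fs).limit_denominator(100000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def _sos_bandpass(low: float, high: float, fs: float, order: int = 2):
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def rereference(raw: WidebandRecording, reference_channels) -> WidebandRecording:
    """Subtract the mean of the reference channels from every signal channel."""
    ref_idx = [list(raw.channel_ids).index(c) if isinstance(c, str) else int(c)
               for c in reference_channels]
    if not ref_idx:
        raise ValueError("reference channel set is empty")
    sig_idx = [i for i in range(raw.samples.shape[1]) if i not in ref_idx]
    ref = raw.samples[:, ref_idx, :].mean(axis=1, keepdims=True)
    out = raw.samples[:, sig_idx, :] - ref
    return WidebandRecording(out, raw.sampling_rate, raw.t0_offset_ms,
                             [raw.channel_ids[i] for i in sig_idx])


def remove_line_noise(trace: np.ndarray, fs: float, line_freq: float = 50.0,
                      t0_offset_ms: float = 0.0,
                      edge_exclude_ms: float = 0.0) -> np.ndarray:
    """Fit and subtract a ``line_freq`` sinusoid per trial (least squares).

    Works on any (..., n_samples) array; amplitude and phase are estimated
    per leading index via the two quadrature regressors.  When the trace
    has passed through a zero-phase filter first, its edges are distorted;
    ``edge_exclude_ms`` drops that margin from the *fit* (the fitted
    sinusoid is still subtracted everywhere).
    """
    x = np.asarray(trace, dtype=float)
    n = x.shape[-1]
    t = (t0_offset_ms / 1000.0) + np.arange(n) / fs
    c = np.cos(2 * np.pi * line_freq * t)
    s = np.sin(2 * np.pi * line_freq * t)
    A = np.stack([c, s], axis=1)                       # (n, 2)
    k = int(round(edge_exclude_ms * fs / 1000.0))
    sl = slice(k, n - k) if 0 < 2 * k < n // 2 else slice(None)
    coef = np.linalg.lstsq(A[sl], x.reshape(-1, n).T[sl], rcond=None)[0]
    fitted = (A @ coef).T.reshape(x.shape)
    return x - fitted


def derive_lfp(raw: WidebandRecording, remove_line: bool = True) -> tuple[np.ndarray, float]:
    """Band-limited (1-200 Hz) field potential at 930 Hz.

    Returns ``(lfp, 930.0)`` with lfp shaped like the input trials.
    """
    if raw.samples.shape[-1] / raw.sampling_rate < 0.25:
        raise ValueError("trial too short to filter stably (need >= 0.25 s)")
    x = _resample(raw.samples, raw.sampling_rate)
    sos = _sos_bandpass(1.0, 200.0, LFP_RATE)
    x = sps.sosfiltfilt(sos, x, axis=-1)
    if remove_line:
        x = remove_line_noise(x, LFP_RATE, t0_offset_ms=raw.t0_offset_ms,
                              edge_exclude_ms=150.0)
    return x, LFP_RATE


def bandpass_spike_band(samples: np.ndarray, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase 500 Hz - 5 kHz band-pass at the native sampling rate."""
    if fs < 10000.0:
        raise ValueError("sampling rate must be >= 10 kHz for spike-band work")
    high = min(5000.0, 0.95 * fs / 2.0)
    sos = _sos_bandpass(500.0, high, fs, order)
    return sps.sosfiltfilt(sos, samples, axis=-1)


def derive_mua_envelope(raw: WidebandRecording) -> tuple[np.ndarray, float]:
    """Rectified spike-band envelope, downsampled to 930 Hz and low-passed < 200 Hz."""
    bp = bandpass_spike_band(raw.samples, raw.sampling_rate)
    env = _resample(np.abs(bp), raw.sampling_rate)
    sos = sps.butter(2, 200.0, btype="lowpass", fs=LFP_RATE, output="sos")
    return sps.sosfiltfilt(sos, env, axis=-1), LFP_RATE


def robust_sigma(x: np.ndarray, convention: str = "divide") -> float:
    """Robust noise-level estimate from the median absolute voltage.

    ``divide``: median(|v|) / 0.6745 (the standard unbiased estimator for
    Gaussian noise); ``multiply``: median(|v|) * 0.6745.
    """
    m = float(np.median(np.abs(x)))
    if convention == "divide":
        return m / 0.6745
    if convention == "multiply":
        return m * 0.6745
    raise ValueError("convention must be 'divide' or 'multiply'")


def detect_spikes(bandpassed: np.ndarray, fs: float, k: float = 3.5,
                  t0_offset_ms: float = 0.0,
                  mad_convention: str = "divide") -> np.ndarray:
    """Threshold-crossing spike times (ms) from one band-passed trial.

    Crossings of ``|v| >= k * sigma_hat`` are logged at the absolute-voltage
    maximum within 0.75 ms after the crossing; further crossings within a
    1.5 ms dead time are ignored.  Positive and negative crossings share one
    dead time.
    """
    v = np.asarray(bandpassed, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite samples in spike-band trace")
    thr = k * robust_sigma(v, mad_convention)
    above = np.abs(v) >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    dead_n = int(round(DEAD_TIME_MS * fs / 1000.0))
    peak_n = max(int(round(PEAK_SEARCH_MS * fs / 1000.0)), 1)
    times = []
    next_allowed = -1
    for i in crossings:
        if i < next_allowed:
            continue
        seg = np.abs(v[i:i + peak_n + 1])
        p = i + int(np.argmax(seg))
        times.append(p)
        next_allowed = i + dead_n
    return t0_offset_ms + np.asarray(times, dtype=float) * 1000.0 / fs


def sdf_kernel() -> np.ndarray:
    """Truncated Gaussian SDF kernel on the 1.1 ms bin grid, renormalized to sum 1."""
    n_bins = int(SDF_KERNEL_MS // SDF_BIN_MS)  # 20 bins -> 22 ms support
    if n_bins % 2 == 0:
        n_bins += 1
    half = n_bins // 2
    t = (np.arange(n_bins) - half) * SDF_BIN_MS
    k = np.exp(-0.5 * (t / SDF_SIGMA_MS) ** 2)
    return k / k.sum()


def spike_density(spike_times_ms: np.ndarray, t_start_ms: float,
                  t_stop_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Spike-density function (spikes/s) on 1.1 ms bins.

    Returns ``(bin_centers_ms, sdf)``.  A single spike integrates to one
    spike because the kernel has unit integral after truncation.
    """
    edges = np.arange(t_start_ms, t_stop_ms + SDF_BIN_MS, SDF_BIN_MS)
    counts, _ = np.histogram(np.asarray(spike_times_ms, dtype=float), bins=edges)
    rate = counts / (SDF_BIN_MS / 1000.0)
    sdf = np.convolve(rate, sdf_kernel(), mode="same")
    centers = edges[:-1] + SDF_BIN_MS / 2.0
    return centers, sdf


def derive_signals(raw: WidebandRecording, k: float = 3.5,
                   mad_convention: str = "divide") -> DerivedSignals:
    """Run the full derivation chain on a trial-segmented recording."""
    lfp, fs_out = derive_lfp(raw)
    mua, _ = derive_mua_envelope(raw)
    bp = bandpass_spike_band(raw.samples, raw.sampling_rate)
    t_stop = raw.t0_offset_ms + raw.samples.shape[-1] * 1000.0 / raw.sampling_rate
    spikes = [[detect_spikes(bp[tr, ch], raw.sampling_rate, k,
                             raw.t0_offset_ms, mad_convention)
               for ch in range(bp.shape[1])] for tr in range(bp.shape[0])]
    centers, _ = spike_density(np.empty(0), raw.t0_offset_ms, t_stop)
    sdf = np.stack([[spike_density(spikes[tr][ch], raw.t0_offset_ms, t_stop)[1]
                     for ch in range(bp.shape[1])] for tr in range(bp.shape[0])])
    return DerivedSignals(lfp, mua, spikes, sdf, fs_out, raw.t0_offset_ms,
                          sdf_times_ms=centers, channel_ids=raw.channel_ids)


# ---------------------------------------------------------------------------
# normalization


NORMALIZATION_SCHEMES = ("rf_map", "max_across_conditions", "center_only_max",
                         "grand_mean_max")


def normalize_mua(traces: np.ndarray, times_ms: np.ndarray, scheme: str,
                  conditions=None, baseline_window=(-200.0, 0.0),
                  rf_window=(50.0, 300.0), peak_window=(30.0, 150.0),
                  center_label: str = "CenterOnly"):
    """Baseline-subtract and scale trial-by-time MUA traces.

    Schemes:

    * ``rf_map``: divide by the window-mean (50-300 ms) response at the
      grid location with the strongest response (requires ``conditions``);
    * ``max_across_conditions``: divide by the peak (30-150 ms) of the
      condition-mean traces, maximized across conditions;
    * ``center_only_max``: divide by the peak of the center-only condition;
    * ``grand_mean_max``: divide by the peak of the grand-mean trace.

    Returns ``(normalized, info)`` where ``info`` records the baseline and
    the normalization denominator.
    """
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    x = np.asarray(traces, dtype=float)
    base = float(x[..., window_mask(times_ms, baseline_window)].mean())
    x = x - base

    pk = window_mask(times_ms, peak_window)
    if scheme == "rf_map":
        if conditions is None:
            raise ValueError("rf_map scheme needs per-trial condition labels")
        w = window_mask(times_ms, rf_window)
        means = pd.Series(x[:, w].mean(axis=1)).groupby(np.asarray(conditions)).mean()
        denom = float(means.max())
    elif scheme == "max_across_conditions":
        if conditions is None:
            raise ValueError("scheme needs per-trial condition labels")
        conds = np.asarray(conditions)
        denom = max(float(x[conds == c][:, pk].mean(axis=0).max())
                    for c in np.unique(conds))
    elif scheme == "center_only_max":
        conds = np.asarray(conditions)
        sel = conds == center_label
        if not sel.any():
            raise ValueError(f"no trials labeled {center_label!r}")
        denom = float(x[sel][:, pk].mean(axis=0).max())
    else:  # grand_mean_max
        denom = float(x[:, pk].mean(axis=0).max())

    if denom <= 0:
        raise ValueError("normalization denominator is not positive")
    return x / denom, {"baseline": base, "denominator": denom, "scheme": scheme}


def welch_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-sample two-sided Welch t-test p-values between two trial groups."""
    return stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
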