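"""Microsaccade detection and fixation-based trial filtering.

Gaze velocity is estimated from position traces smoothed with a 5-sample
boxcar, using a central difference over +/-2 samples (this suppresses the
quantization noise that would otherwise cross a 10 deg/s threshold
spuriously at 1 kHz).  A microsaccade is a maximal run of samples with
speed above threshold lasting at least ``min_dur_ms``; runs separated by
less than 5 ms are merged into one event.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu

from .types import EyeTrace, MicrosaccadeEvent, window_mask

MERGE_GAP_MS = 5.0


def _smooth(x: np.ndarray, n: int = 5) -> np.ndarray:
    k = np.ones(n) / n
    return np.convolve(x, k, mode="same")


def gaze_speed(x: np.ndarray, y: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Instantaneous gaze speed (deg/s) from one trial's position traces."""
    xs, ys = _smooth(x), _smooth(y)
    dt = 4.0 / fs  # central difference over +/- 2 samples
    vx = np.zeros_like(xs)
    vy = np.zeros_like(ys)
    vx[2:-2] = (xs[4:] - xs[:-4]) / dt
    vy[2:-2] = (ys[4:] - ys[:-4]) / dt
    return np.hypot(vx, vy)


def detect_microsaccades(trace: EyeTrace, vthresh: float = 10.0,
                         min_dur_ms: float = 10.0, trial: int = 0):
    """Detect microsaccades in one trial of an eye trace.

    Returns a list of :class:`MicrosaccadeEvent` with onset/offset (ms,
    stimulus-relative), peak velocity and amplitude (straight-line gaze
    displacement over the event).
    """
    fs = trace.sampling_rate
    x, y = trace.x[trial], trace.y[trial]
    if x.size < min_dur_ms * fs / 1000.0:
        raise ValueError("trace shorter than the minimum event duration")
    speed = gaze_speed(x, y, fs)
    above = speed > vthresh

    # maximal runs of suprathreshold samples
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)

    # merge runs separated by < 5 ms
    merged = []
    gap_n = MERGE_GAP_MS * fs / 1000.0
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_n = min_dur_ms * fs / 1000.0
    t = trace.times_ms
    events = []
    for s, e in merged:
        if e - s < min_n:
            continue
        amp = float(np.hypot(x[e - 1] - x[s], y[e - 1] - y[s]))
        events.append(MicrosaccadeEvent(
            onset_ms=float(t[s]), offset_ms=float(t[e - 1]),
            peak_velocity=float(speed[s:e].max()), amplitude=amp))
    return events


def fixation_filter(trial_ids, eye: EyeTrace, radius_deg: float = 1.0,
                    window=(0.0, 500.0), center=(0.0, 0.0)):
    """Trial ids whose gaze stays within ``radius_deg`` of the fixation center.

    A 2 deg radius is the typical online abort criterion; offline analyses
    of contextual/attentional data use a stricter 1 deg.
    """
    trial_ids = np.asarray(trial_ids)
    if trial_ids.max(initial=-1) >= eye.x.shape[0]:
        raise ValueError("missing eye data for requested trial")
    m = window_mask(eye.times_ms, window)
    r = np.hypot(eye.x[:, m] - center[0], eye.y[:, m] - center[1])
    kept = trial_ids[r[trial_ids].max(axis=1) <= radius_deg]
    return kept


def reject_microsaccade_trials(eye: EyeTrace, vthresh: float = 10.0,
                               min_dur_ms: float = 10.0, window=(0.0, 500.0)):
    """Trial ids without any detected microsaccade inside ``window``."""
    keep = []
    for k in range(eye.x.shape[0]):
        events = detect_microsaccades(eye, vthresh, min_dur_ms, trial=k)
        bad = any(window[0] <= ev.onset_ms < window[1] for ev in events)
        if not bad:
            keep.append(k)
    return np.asarray(keep, dtype=int)


def eye_condition_stats(eye: EyeTrace, conditions, group_a, group_b,
                        window=(0.0, 500.0)) -> dict:
    """Mann-Whitney U tests on trial-mean x, y and speed between two groups.

    ``group_a``/``group_b`` are condition labels (or collections of labels);
    returns per-group means and the U-test p-values for x-position,
    y-position and velocity.
    """
    conds = np.asarray(conditions)
    ga = {group_a} if isinstance(group_a, str) else set(group_a)
    gb = {group_b} if isinstance(group_b, str) else set(group_b)
    ia = np.flatnonzero(np.isin(conds, list(ga)))
    ib = np.flatnonzero(np.isin(conds, list(gb)))
    if ia.size < 2 or ib.size < 2:
        raise ValueError("need at least 2 trials per condition group")
    m = window_mask(eye.times_ms, window)
    mx = eye.x[:, m].mean(axis=1)
    my = eye.y[:, m].mean(axis=1)
    ms = np.array([gaze_speed(eye.x[k], eye.y[k], eye.sampling_rate)[m].mean()
                   for k in range(eye.x.shape[0])])
    out = {}
    for name, v in (("x", mx), ("y", my), ("speed", ms)):
        out[f"mean_{name}_a"] = float(v[ia].mean())
        out[f"mean_{name}_b"] = float(v[ib].mean())
        out[f"p_{name}"] = float(mannwhitneyu(v[ia], v[ib]).pvalue)
    return out
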