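"""Receptive-field estimation from grid-flash responses.

A response map (mean windowed activity per grid location, max-normalized)
is fit with a 2-D elliptical Gaussian

    R(x, y) = exp(-(a dx^2 + 2 b dx dy + c dy^2))

with dx = x - rf_x, dy = y - rf_y and (a, b, c) built from sigma_x, sigma_y
and the orientation theta.  RF size is reported as the FWHM averaged over
the x and y axes.  Response latency is the first sample at which near-RF
and far-from-RF trials differ significantly, sustained over a run of
consecutive significant samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .signals import welch_t_pvalues
from .types import FWHM_PER_SIGMA, RFFit, window_mask

DEFAULT_WINDOWS = {"mua": (50.0, 300.0), "gamma_power": (100.0, 250.0)}


@dataclass
class ResponseMap:
    """Grid of max-normalized responses, ready for Gaussian fitting."""

    xs: np.ndarray         # unique x coordinates (deg), sorted
    ys: np.ndarray         # unique y coordinates (deg), sorted
    values: np.ndarray     # (len(ys), len(xs))
    window: tuple
    kind: str = "mua"
    all_zero: bool = False


def build_response_map(traces: np.ndarray, times_ms: np.ndarray,
                       stimuli: pd.DataFrame, window=None,
                       signal_kind: str = "mua") -> ResponseMap:
    """Average windowed responses per grid location and max-normalize.

    ``traces`` is (n_trials, n_t) — typically normalized MUA — or a
    per-trial scalar vector (n_trials,) for precomputed quantities such as
    relative gamma power (pass ``signal_kind='gamma_power'``).
    """
    if signal_kind not in DEFAULT_WINDOWS:
        raise ValueError(f"signal_kind must be one of {tuple(DEFAULT_WINDOWS)}")
    window = tuple(window) if window is not None else DEFAULT_WINDOWS[signal_kind]
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 2:
        m = window_mask(times_ms, window)
        if not m.any():
            raise ValueError(f"window {window} lies outside the data range")
        per_trial = traces[:, m].mean(axis=1)
    else:
        per_trial = traces

    df = pd.DataFrame({"x": stimuli["grid_x"].to_numpy(),
                       "y": stimuli["grid_y"].to_numpy(),
                       "r": per_trial})
    mean = df.groupby(["y", "x"])["r"].agg(["mean", "count"]).reset_index()
    if (mean["count"] == 0).any():
        raise ValueError("grid location with zero trials")
    xs = np.unique(mean["x"])
    ys = np.unique(mean["y"])
    grid = mean.pivot(index="y", columns="x", values="mean").to_numpy()
    if np.isnan(grid).any():
        raise ValueError("grid location with zero trials")
    peak = grid.max()
    if peak <= 0:
        return ResponseMap(xs, ys, np.zeros_like(grid), window, signal_kind, all_zero=True)
    return ResponseMap(xs, ys, grid / peak, window, signal_kind)


def gauss2d(x, y, rf_x, rf_y, sigma_x, sigma_y, theta, amplitude=1.0):
    """Elliptical 2-D Gaussian in the (a, b, c) quadratic-form parameterization."""
    a = np.cos(theta) ** 2 / (2 * sigma_x ** 2) + np.sin(theta) ** 2 / (2 * sigma_y ** 2)
    b = -np.sin(2 * theta) / (4 * sigma_x ** 2) + np.sin(2 * theta) / (4 * sigma_y ** 2)
    c = np.sin(theta) ** 2 / (2 * sigma_x ** 2) + np.cos(theta) ** 2 / (2 * sigma_y ** 2)
    dx, dy = x - rf_x, y - rf_y
    return amplitude * np.exp(-(a * dx ** 2 + 2 * b * dx * dy + c * dy ** 2))


def _moments_init(rmap: ResponseMap):
    gx, gy = np.meshgrid(rmap.xs, rmap.ys)
    w = np.clip(rmap.values, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return np.array([rmap.xs.mean(), rmap.ys.mean(), 1.0, 1.0, 0.0])
    mx = (w * gx).sum() / tot
    my = (w * gy).sum() / tot
    sx = np.sqrt(np.clip((w * (gx - mx) ** 2).sum() / tot, 1e-3, None))
    sy = np.sqrt(np.clip((w * (gy - my) ** 2).sum() / tot, 1e-3, None))
    # argmax gives a sharper center estimate than the centroid on broad maps
    iy, ix = np.unravel_index(np.argmax(rmap.values), rmap.values.shape)
    return np.array([rmap.xs[ix], rmap.ys[iy], sx, sy, 0.0])


def fit_rf_gaussian(rmap: ResponseMap, n_restarts: int = 8,
                    fit_amplitude: bool = False, seed: int = 0) -> RFFit:
    """Least-squares elliptical Gaussian fit of a response map.

    Nelder-Mead on the sum of squared residuals with jittered multi-starts
    (the objective is multimodal in theta).  Widths are optimized on a log
    scale to stay positive.  Non-convergence and degenerate (all-zero) maps
    are flagged, not raised.
    """
    if rmap.values.size < 9:
        raise ValueError("need at least 9 grid locations")
    if rmap.all_zero or rmap.values.max() <= 0:
        return RFFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                     fit_rss=np.nan, converged=False)
    gx, gy = np.meshgrid(rmap.xs, rmap.ys)
    data = rmap.values
    rng = np.random.default_rng(seed)

    def unpack(p):
        rf_x, rf_y, lsx, lsy, theta = p[:5]
        amp = p[5] if fit_amplitude else 1.0
        return rf_x, rf_y, np.exp(lsx), np.exp(lsy), theta, amp

    def cost(p):
        rf_x, rf_y, sx, sy, theta, amp = unpack(p)
        return float(((gauss2d(gx, gy, rf_x, rf_y, sx, sy, theta, amp) - data) ** 2).sum())

    x0, y0, sx0, sy0, th0 = _moments_init(rmap)
    base = [x0, y0, np.log(sx0), np.log(sy0), th0]
    if fit_amplitude:
        base.append(1.0)
    best = None
    for r in range(max(n_restarts, 1)):
        p0 = np.array(base, dtype=float)
        if r > 0:
            p0[:2] += rng.normal(0, 0.5, 2)
            p0[2:4] += rng.normal(0, 0.3, 2)
            p0[4] = rng.uniform(0, np.pi)
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    rf_x, rf_y, sx, sy, theta, _ = unpack(best.x)
    theta = theta % np.pi
    fwhm = FWHM_PER_SIGMA * (sx + sy) / 2.0
    return RFFit(rf_x, rf_y, sx, sy, theta, fwhm, fit_rss=float(best.fun),
                 converged=bool(best.success))


def response_latency(near_trials: np.ndarray, far_trials: np.ndarray,
                     times_ms: np.ndarray, alpha: float = 0.05,
                     run_length: int = 10):
    """Onset latency (ms): first significant sample followed by ``run_length``
    contiguous significant per-sample Welch t-tests between the trial groups.

    Returns ``None`` when no such run exists (e.g. identical groups).
    Only samples at t >= 0 are considered.
    """
    near = np.atleast_2d(near_trials)
    far = np.atleast_2d(far_trials)
    if near.shape[1] != far.shape[1]:
        raise ValueError("trial groups have unequal lengths")
    if near.shape[0] < 2 or far.shape[0] < 2:
        raise ValueError("need at least 2 trials per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = welch_t_pvalues(near, far)
    sig = (p < alpha) & (times_ms >= 0.0)
    need = run_length + 1
    for i in range(sig.size - need + 1):
        if sig[i:i + need].all():
            return float(times_ms[i])
    return None


def split_near_far(stimuli: pd.DataFrame, center, fraction: float = 0.10):
    """Trial indices of the ~10% of grid locations closest/farthest from ``center``.

    The location count is rounded to nearest (an 11 x 11 grid yields 12).
    """
    locs = stimuli[["grid_x", "grid_y"]].drop_duplicates().to_numpy()
    d = np.hypot(locs[:, 0] - center[0], locs[:, 1] - center[1])
    n = max(int(round(fraction * len(locs))), 1)
    order = np.argsort(d)
    near_locs = {tuple(l) for l in locs[order[:n]]}
    far_locs = {tuple(l) for l in locs[order[-n:]]}
    pts = list(zip(stimuli["grid_x"], stimuli["grid_y"]))
    near = np.array([p in near_locs for p in pts])
    far = np.array([p in far_locs for p in pts])
    return np.flatnonzero(near), np.flatnonzero(far)
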