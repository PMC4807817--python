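"""Orientation, contrast and size tuning: models, fits and significance.

Tuning strength is one minus the circular variance of the response-weighted
angle distribution,

    1-CircVar = |sum_k R(theta_k) e^{2 i theta_k}| / sum_k R(theta_k)

(angle doubling for orientation; plain angles for direction).  Its
significance comes from a bootstrap null in which trial responses are
resampled with replacement and shuffled across stimulus angles.  Tuning
curves are fit with a wrapped Gaussian, contrast-response curves with the
Naka-Rushton equation, and size-tuning curves with an erf-based
ratio-of-Gaussians model whose surround index is
SI = (Rmax - Rsupp) / Rmax.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .synthetic import ang_ori, naka_rushton, rog_response
from .types import HWHM_PER_SIGMA, ContrastFit, OrientationFit, SizeFit


def circular_variance_tuning(responses, angles_rad, mode: str = "orientation") -> float:
    """1-CircVar in [0, 1]: 0 for untuned, 1 for perfectly concentrated.

    ``angles_rad`` are stimulus angles in radians; orientation mode doubles
    them so that 0 and 180 deg coincide.  Negative (baseline-subtracted)
    responses are clipped at zero — the statistic assumes nonnegative
    weights.
    """
    if mode not in ("orientation", "direction"):
        raise ValueError("mode must be 'orientation' or 'direction'")
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    th = np.asarray(angles_rad, dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("all responses are zero after clipping")
    factor = 2.0 if mode == "orientation" else 1.0
    return float(np.abs(np.sum(r * np.exp(1j * factor * th))) / total)


def condition_means(trial_responses, angles_rad):
    """Mean response per unique angle; returns (unique_angles, means)."""
    th = np.asarray(angles_rad, dtype=float)
    r = np.asarray(trial_responses, dtype=float)
    uniq = np.unique(th)
    means = np.array([r[th == u].mean() for u in uniq])
    return uniq, means


def bootstrap_tuning_p(trial_responses, angles_rad, mode: str = "orientation",
                       n_boot: int = 10000, seed: int | None = None) -> float:
    """Bootstrap p-value of the tuning strength.

    The observed statistic is 1-CircVar of the per-angle condition means.
    Null draws resample the trial responses with replacement and assign them
    to the original angle labels (shuffling response-angle pairings), then
    recompute the statistic.  p = (1 + #{null >= observed}) / (1 + n_boot),
    which avoids p = 0.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    r = np.asarray(trial_responses, dtype=float)
    th = np.asarray(angles_rad, dtype=float)
    uniq, means = condition_means(r, th)
    counts = np.array([(th == u).sum() for u in uniq])
    if (counts < 2).any():
        raise ValueError("need at least 2 trials per condition")
    observed = circular_variance_tuning(means, uniq, mode)

    rng = np.random.default_rng(seed)
    n = r.size
    factor = 2.0 if mode == "orientation" else 1.0
    phase = np.exp(1j * factor * uniq)
    masks = [th == u for u in uniq]
    null = np.empty(n_boot)
    batch = 500
    for start in range(0, n_boot, batch):
        b = min(batch, n_boot - start)
        draws = r[rng.integers(0, n, size=(b, n))]
        cm = np.stack([draws[:, m].mean(axis=1) for m in masks], axis=1)
        cm = np.clip(cm, 0.0, None)
        tot = cm.sum(axis=1)
        tot[tot <= 0] = np.nan
        null[start:start + b] = np.abs(cm @ phase) / tot
    null = np.nan_to_num(null, nan=0.0)
    return float((1 + np.sum(null >= observed)) / (1 + n_boot))


def orientation_gaussian(theta_deg, C, Rp, theta_pref, sigma):
    """Wrapped Gaussian R(theta) = C + Rp exp(-ang_ori(theta - theta_pref)^2 / 2 sigma^2)."""
    d = ang_ori(np.asarray(theta_deg, dtype=float) - theta_pref)
    return C + Rp * np.exp(-d ** 2 / (2.0 * sigma ** 2))


def fit_orientation_gaussian(mean_responses, orientations_deg) -> OrientationFit:
    """Least-squares wrapped-Gaussian fit of condition-mean responses.

    Multi-starts over candidate preferred orientations guard against local
    minima.  Flat data yield Rp ~ 0 and ``tuned=False`` (the preferred
    orientation is then undefined).
    """
    r = np.asarray(mean_responses, dtype=float)
    th = np.asarray(orientations_deg, dtype=float) % 180.0
    if np.unique(th).size < 6:
        raise ValueError("need at least 6 distinct orientations")
    span = float(np.ptp(r))
    scale = max(span, 1e-12)

    def resid(p):
        return orientation_gaussian(th, *p) - r

    best = None
    for th0 in np.unique(th):
        p0 = [float(r.min()), span if span > 0 else 1e-3, float(th0), 30.0]
        res = least_squares(resid, p0,
                            bounds=([-np.inf, 0.0, -360.0, 1.0],
                                    [np.inf, np.inf, 720.0, 180.0]))
        if best is None or res.cost < best.cost:
            best = res
    C, Rp, th_pref, sigma = best.x
    tuned = Rp > 0.05 * scale and span > 0
    return OrientationFit(C=float(C), Rp=float(Rp),
                          theta_pref=float(th_pref % 180.0), sigma=float(sigma),
                          hwhm=float(HWHM_PER_SIGMA * sigma),
                          converged=bool(best.success), tuned=bool(tuned))


def fit_naka_rushton(mean_responses, contrasts) -> ContrastFit:
    """Naka-Rushton fit R(x) = b x^N / (C50^N + x^N), C50 in % contrast.

    The exponent is bounded to [0.5, 6] to avoid degenerate step-like fits.
    """
    r = np.asarray(mean_responses, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 contrast levels")
    if np.ptp(r) <= 0:
        raise ValueError("responses are all equal; contrast fit undefined")

    def resid(p):
        return naka_rushton(c, *p) - r

    best = None
    for c50_0 in (2.0, 5.0, 10.0, 25.0, 50.0):
        p0 = [max(r.max(), 1e-6), 2.0, c50_0]
        res = least_squares(resid, p0,
                            bounds=([0.0, 0.5, 0.1], [np.inf, 6.0, 500.0]))
        if best is None or res.cost < best.cost:
            best = res
    b, N, c50 = best.x
    return ContrastFit(b=float(b), N=float(N), c50=float(c50),
                       converged=bool(best.success))


def fit_rog_size(mean_responses, sizes, max_size: float | None = None) -> SizeFit:
    """Ratio-of-Gaussians size-tuning fit with surround index.

    ``optimal_size`` is the argmax of the fitted model on a fine grid over
    [0, max tested size]; SI = (Rmax - R(max size)) / Rmax.  Monotonically
    increasing data legitimately give SI ~ 0.
    """
    r = np.asarray(mean_responses, dtype=float)
    x = np.asarray(sizes, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 size levels")
    xmax = float(max_size if max_size is not None else x.max())
    rmax_data = max(r.max(), 1e-9)

    def resid(p):
        return rog_response(x, *p) - r

    best = None
    x_at_max = float(x[np.argmax(r)])
    for wi_scale in (2.0, 3.0, 5.0):
        p0 = [2.0 * rmax_data, 1.0, max(x_at_max, 0.5), wi_scale * max(x_at_max, 0.5)]
        res = least_squares(resid, p0,
                            bounds=([0.0, 0.0, 1e-2, 1e-2],
                                    [np.inf, np.inf, 10 * xmax, 20 * xmax]))
        if best is None or res.cost < best.cost:
            best = res
    ge, gi, we, wi = best.x
    grid = np.linspace(0.0, xmax, 2000)
    model = rog_response(grid, ge, gi, we, wi)
    rmax = float(model.max())
    rsupp = float(rog_response(xmax, ge, gi, we, wi))
    si = 0.0 if rmax <= 0 else float((rmax - rsupp) / rmax)
    return SizeFit(Ge=float(ge), Gi=float(gi), We=float(we), Wi=float(wi),
                   si=si, optimal_size=float(grid[np.argmax(model)]),
                   converged=bool(best.success))


def window_mean_responses(traces: np.ndarray, times_ms: np.ndarray,
                          window=(0.0, 500.0)) -> np.ndarray:
    """Per-trial mean response in the analysis window (default 0-0.5 s)."""
    from .types import window_mask
    return np.asarray(traces, dtype=float)[:, window_mask(times_ms, window)].mean(axis=1)
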