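"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* time is expressed in milliseconds relative to stimulus onset (onset = 0),
  analysis windows are half-open ``[start, end)``;
* motion directions are measured counterclockwise from rightward 0-345 deg,
  orientation = direction mod 180;
* voltages are in microvolts, firing rates in spikes/s, visual angles in
  degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: full width at half maximum of a Gaussian, in units of its sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
#: half width at half maximum, in units of sigma
HWHM_PER_SIGMA = np.sqrt(2.0 * np.log(2.0))


@dataclass
class WidebandRecording:
    """Trial-segmented raw extracellular voltage.

    ``samples`` has shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    ``t0_offset_ms`` is the time of the first sample relative to stimulus
    onset (negative: recording starts before the stimulus).
    """

    samples: np.ndarray
    sampling_rate: float
    t0_offset_ms: float
    channel_ids: Sequence[str] = field(default_factory=lambda: ("ch0",))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:  # single channel convenience
            self.samples = self.samples[:, None, :]
        if self.samples.ndim != 3:
            raise ValueError("samples must be (n_trials, n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.samples.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.samples.shape[-1]
        return self.t0_offset_ms + np.arange(n) * 1000.0 / self.sampling_rate


@dataclass
class DerivedSignals:
    """LFP, MUA envelope, thresholded spike times and spike-density functions.

    LFP and MUA envelope share the same (downsampled) time base.  Spike times
    are per trial and channel, in ms relative to stimulus onset.  The SDF is
    evaluated on 1.1 ms bins (``sdf_times_ms``) in spikes/s.
    """

    lfp: np.ndarray                    # (n_trials, n_channels, n_t)
    mua_envelope: np.ndarray           # same shape/time base as lfp
    spike_times: list                  # [trial][channel] -> ndarray of ms
    sdf: np.ndarray                    # (n_trials, n_channels, n_bins)
    sampling_rate: float               # of lfp / mua_envelope (930 Hz)
    t0_offset_ms: float
    sdf_times_ms: np.ndarray = None
    channel_ids: Sequence[str] = field(default_factory=lambda: ("ch0",))

    @property
    def times_ms(self) -> np.ndarray:
        n = self.lfp.shape[-1]
        return self.t0_offset_ms + np.arange(n) * 1000.0 / self.sampling_rate


@dataclass
class EyeTrace:
    """Horizontal/vertical gaze position in degrees, sampled at 1 kHz.

    ``x`` and ``y`` have shape ``(n_trials, n_samples)``.
    """

    x: np.ndarray
    y: np.ndarray
    sampling_rate: float = 1000.0
    t0_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have identical shapes")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.x.shape[-1]) * 1000.0 / self.sampling_rate


@dataclass
class GroundTruth:
    """True generative parameters of a simulated session.

    Every fitted quantity downstream has a counterpart here so each analysis
    stage can be verified by parameter recovery.  Rate-model parameters:

    * receptive field: 2-D Gaussian gain centred at ``rf_center`` with width
      ``rf_sigma`` (isotropic);
    * orientation: wrapped Gaussian around ``pref_orientation`` with width
      ``tuning_width_sigma``;
    * contrast: Naka-Rushton with ``c50_true`` (% contrast) and exponent
      ``naka_exponent``;
    * size: ratio-of-Gaussians with ``rog_params = (Ge, Gi, We, Wi)``;
    * context/attention: per-condition additive rate offsets (spikes/s) with
      their own onset latencies, in ``modulation[cond] = [(offset, onset_ms)]``.

    Gamma amplitude (relative units of the session's base gamma amplitude)
    and frequency (Hz) may be given per condition; when left ``None`` they
    follow the firing-rate tuning gain of the condition.
    """

    rf_center: tuple = (10.0, -2.5)
    rf_sigma: float = 1.87            # FWHM ~ 4.4 deg
    pref_orientation: float = 171.0   # deg, in [0, 180)
    tuning_width_sigma: float = 49.0  # deg; HWHM ~ 58 deg
    baseline_rate: float = 15.0       # spikes/s (multi-unit aggregate)
    peak_rate: float = 150.0          # spikes/s
    c50_true: float = 7.3             # % contrast
    naka_exponent: float = 2.0
    rog_params: tuple = (2.0, 1.0, 2.0, 6.0)   # (Ge, Gi, We, Wi)
    gamma_amp_per_condition: Optional[dict] = None
    gamma_freq_per_condition: Optional[dict] = None
    gamma_base_freq: float = 55.0     # Hz
    response_latency_true: float = 57.0  # ms
    modulation: Optional[dict] = None
    # firing-rate adaptation: the stimulus-driven rate decays from its onset
    # transient to sustained_fraction with time constant adapt_tau_ms
    sustained_fraction: float = 0.5
    adapt_tau_ms: float = 100.0
    # contextual/attentional offsets develop over mod_rise_ms and then decay
    # toward mod_sustained with time constant mod_tau_ms
    mod_rise_ms: float = 50.0
    mod_sustained: float = 0.3
    mod_tau_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rf_sigma <= 0:
            raise ValueError("rf_sigma must be positive")
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("require peak_rate >= baseline_rate >= 0")
        ge, gi, we, wi = self.rog_params
        if we <= 0 or wi <= 0:
            raise ValueError("ROG widths We, Wi must be positive")
        if self.response_latency_true < 0:
            raise ValueError("latencies must be nonnegative")
        if self.modulation:
            for offsets in self.modulation.values():
                for entry in offsets:
                    if entry[1] < 0:
                        raise ValueError("modulation onsets must be nonnegative")


@dataclass
class SyntheticDataset:
    """A complete simulated session: recording + stimuli + eye + ground truth."""

    recording: WidebandRecording
    stimuli: pd.DataFrame
    eye: EyeTrace
    truth: GroundTruth

    def __post_init__(self) -> None:
        n = self.recording.n_trials
        if len(self.stimuli) != n or self.eye.x.shape[0] != n:
            raise ValueError("trial counts disagree across recording/stimuli/eye")


# ---------------------------------------------------------------------------
# fit-result bundles


@dataclass
class RFFit:
    """2-D elliptical Gaussian receptive-field fit."""

    rf_x: float
    rf_y: float
    sigma_x: float
    sigma_y: float
    theta: float          # radians
    fwhm: float           # deg, mean of x/y FWHMs
    fit_rss: float
    converged: bool


@dataclass
class OrientationFit:
    """Wrapped (circular) Gaussian orientation-tuning fit."""

    C: float
    Rp: float
    theta_pref: float     # deg, [0, 180)
    sigma: float          # deg
    hwhm: float           # deg
    one_minus_circvar: float = np.nan
    p_boot: float = np.nan
    converged: bool = True
    tuned: bool = True    # False when Rp is indistinguishable from flat


@dataclass
class ContrastFit:
    """Naka-Rushton contrast-response fit; c50 in % contrast."""

    b: float
    N: float
    c50: float
    converged: bool = True


@dataclass
class SizeFit:
    """Ratio-of-Gaussians size-tuning fit with surround suppression index."""

    Ge: float
    Gi: float
    We: float
    Wi: float
    si: float
    optimal_size: float
    converged: bool = True


@dataclass
class GammaPeakFit:
    """Gaussian fit to the relative gamma power spectrum."""

    G: float
    mu: float             # Hz
    sigma: float          # Hz
    b_offset: float
    fit_range: tuple
    peak_height: float    # G / (sqrt(2 pi) sigma)
    no_peak: bool


@dataclass
class ModulationResult:
    """Contextual modulation time course with window statistics and latency."""

    timecourse: np.ndarray
    times_ms: np.ndarray
    early_mean: float
    late_mean: float
    p_early: float
    p_late: float
    latency_ms: Optional[float]
    gauss_params: Optional[tuple]   # (amplitude, center, width, offset)
    early_window: tuple = (50.0, 100.0)
    late_window: tuple = (100.0, 500.0)


@dataclass
class AttentionResult:
    """Target vs distractor modulation in the curve-tracing task."""

    target_mean_early: float
    target_mean_late: float
    distractor_mean_early: float
    distractor_mean_late: float
    p_early: float
    p_late: float
    near_vs_far_p: float
    early_window: tuple = (0.0, 150.0)
    late_window: tuple = (200.0, 500.0)


@dataclass
class MicrosaccadeEvent:
    """A fixational saccade detected by sustained velocity-threshold crossing."""

    onset_ms: float
    offset_ms: float
    peak_velocity: float  # deg/s
    amplitude: float      # deg


def window_mask(times_ms: np.ndarray, window) -> np.ndarray:
    """Boolean mask for the half-open window [start, end) in ms."""
    lo, hi = window
    return (times_ms >= lo) & (times_ms < hi)
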