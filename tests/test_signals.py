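"""Signal-derivation chain: re-referencing, LFP, line removal, MUA envelope,
spike detection and spike-density functions."""

import numpy as np
import pytest
from scipy import signal as sps

from vistune import signals
from vistune.types import WidebandRecording

FS = 12500.0


def make_rec(x, fs=FS, t0=0.0):
    return WidebandRecording(np.atleast_2d(x)[None, :, :]
                             if np.ndim(x) == 2 else np.asarray(x)[None, None, :],
                             fs, t0)


# ---------------------------------------------------------------------------
# rereference


def test_rereference_duplicated_reference_cancels(rng):
    x = rng.standard_normal((1, 2, 1000))
    x[:, 1] = x[:, 0]          # signal == reference
    rec = WidebandRecording(x, FS, 0.0, ["sig", "ref"])
    out = signals.rereference(rec, ["ref"])
    np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)


def test_rereference_symmetric_references_are_neutral(rng):
    x = rng.standard_normal((2, 3, 500))
    x[:, 1] = 1.0
    x[:, 2] = -1.0
    rec = WidebandRecording(x, FS, 0.0, ["sig", "p", "m"])
    out = signals.rereference(rec, ["p", "m"])
    np.testing.assert_allclose(out.samples[:, 0], x[:, 0], atol=1e-12)


def test_rereference_matches_naive_loop(rng):
    x = rng.standard_normal((3, 4, 200))
    rec = WidebandRecording(x, FS, 0.0, ["a", "b", "r1", "r2"])
    out = signals.rereference(rec, ["r1", "r2"])
    for tr in range(3):
        for ch, name in enumerate(["a", "b"]):
            expected = x[tr, ch] - (x[tr, 2] + x[tr, 3]) / 2.0
            np.testing.assert_allclose(out.samples[tr, ch], expected)


def test_rereference_empty_reference_set_rejected(rng):
    rec = WidebandRecording(rng.standard_normal((1, 2, 100)), FS, 0.0, ["a", "b"])
    with pytest.raises(ValueError, match="empty"):
        signals.rereference(rec, [])


# ---------------------------------------------------------------------------
# LFP


def test_lfp_attenuates_300hz_per_butterworth_response():
    # zero-phase 2nd-order Butterworth low edge 200 Hz: amplitude factor at
    # 300 Hz is 1/(1 + (300/200)^4) ~ 0.165 (-15.6 dB); the full chain
    # (resampling + high-pass) attenuates slightly more
    t = np.arange(int(FS)) / FS
    rec = make_rec(np.sin(2 * np.pi * 300 * t))
    lfp, fs_out = signals.derive_lfp(rec, remove_line=False)
    out_rms = lfp[0, 0, 200:-200].std()
    assert fs_out == 930.0
    assert out_rms < np.sqrt(0.5) / (1 + (300 / 200) ** 4)


def test_lfp_removes_dc():
    rec = make_rec(np.full(int(FS), 7.0))
    lfp, _ = signals.derive_lfp(rec, remove_line=False)
    assert abs(lfp[0, 0, 200:-200].mean()) < 0.05 * 7.0


def test_lfp_suppresses_50hz_line():
    # evaluated in the filter's steady state: near the trial edges the 1 Hz
    # zero-phase high-pass modulates the sine's amplitude, which a global
    # 50 Hz fit cannot (and should not) absorb
    t = np.arange(int(3 * FS)) / FS
    rec = make_rec(10.0 * np.sin(2 * np.pi * 50 * t + 0.3))
    lfp, _ = signals.derive_lfp(rec, remove_line=True)
    x = lfp[0, 0]
    third = x.size // 3
    assert x[third:-third].std() < 0.05 * 10.0 * np.sqrt(0.5)


def test_lfp_rejects_too_short_trials():
    rec = make_rec(np.zeros(100))
    with pytest.raises(ValueError, match="short"):
        signals.derive_lfp(rec)


# ---------------------------------------------------------------------------
# line-noise removal


def test_line_fit_subtracts_pure_sine_exactly():
    t = np.arange(2000) / 930.0
    x = 3.0 * np.sin(2 * np.pi * 50 * t + 0.7)
    out = signals.remove_line_noise(x, 930.0)
    assert np.abs(out).max() < 1e-6 * 3.0


def test_line_fit_is_noop_on_broadband_noise(rng):
    x = rng.standard_normal(2000)
    out = signals.remove_line_noise(x, 930.0)
    assert np.corrcoef(x, out)[0, 1] > 0.995


def test_line_fit_recovers_amplitude_in_noise(rng):
    t = np.arange(4000) / 930.0
    amp, phase = 3.0, 0.7
    clean = amp * np.sin(2 * np.pi * 50 * t + phase)
    x = clean + rng.standard_normal(t.size)
    out = signals.remove_line_noise(x, 930.0)
    resid = out - (x - clean)           # = clean - fitted
    # closed-form LS on two quadrature regressors: SE(amp) ~ sigma*sqrt(2/n)
    assert np.sqrt(2 * (resid ** 2).mean()) < 4 * np.sqrt(2.0 / t.size) * 3


# ---------------------------------------------------------------------------
# MUA envelope


def test_mua_envelope_zero_input_zero_output():
    rec = make_rec(np.zeros(int(FS)))
    env, fs_out = signals.derive_mua_envelope(rec)
    assert fs_out == 930.0
    np.testing.assert_allclose(env, 0.0, atol=1e-12)


def spike_train_trace(times_ms, n_ms=1000.0, amp=30.0):
    from vistune.synthetic import spike_template
    n = int(FS * n_ms / 1000.0)
    x = np.zeros(n)
    w = spike_template(FS, amp)
    for tm in times_ms:
        i = int(round(tm * FS / 1000.0))
        x[i:i + w.size] += w
    return x


def test_mua_envelope_peaks_at_inserted_spike_times():
    times = [200.0, 400.0, 650.0]
    rec = make_rec(spike_train_trace(times))
    env, fs_out = signals.derive_mua_envelope(rec)
    e = env[0, 0]
    t = np.arange(e.size) * 1000.0 / fs_out
    for tm in times:
        m = (t >= tm - 10) & (t <= tm + 10)
        assert abs(t[m][np.argmax(e[m])] - tm) <= 2.0


def test_mua_envelope_scales_linearly_with_amplitude():
    rec1 = make_rec(spike_train_trace([500.0], amp=20.0))
    rec2 = make_rec(spike_train_trace([500.0], amp=40.0))
    e1, _ = signals.derive_mua_envelope(rec1)
    e2, _ = signals.derive_mua_envelope(rec2)
    assert e2.max() == pytest.approx(2.0 * e1.max(), rel=1e-6)


def test_mua_envelope_requires_10khz():
    rec = make_rec(np.zeros(5000), fs=5000.0)
    with pytest.raises(ValueError, match="10 kHz"):
        signals.derive_mua_envelope(rec)


# ---------------------------------------------------------------------------
# spike detection


def test_single_large_spike_yields_one_event_at_peak():
    x = spike_train_trace([500.0], amp=50.0)
    x += 0.1 * np.sin(2 * np.pi * 1000 * np.arange(x.size) / FS)  # sets sigma-hat
    times = signals.detect_spikes(x, FS, k=3.5)
    assert times.size == 1
    peak_ms = np.argmax(np.abs(x)) * 1000.0 / FS
    assert times[0] == pytest.approx(peak_ms, abs=0.1)


def test_two_spikes_within_dead_time_merge():
    x = spike_train_trace([500.0, 501.0], amp=50.0)
    x += 0.1 * np.sin(2 * np.pi * 1000 * np.arange(x.size) / FS)
    assert signals.detect_spikes(x, FS).size == 1
    y = spike_train_trace([500.0, 503.0], amp=50.0)
    y += 0.1 * np.sin(2 * np.pi * 1000 * np.arange(y.size) / FS)
    assert signals.detect_spikes(y, FS).size == 2


def test_detect_spikes_rejects_nonfinite():
    x = np.zeros(1000)
    x[10] = np.nan
    with pytest.raises(ValueError, match="finite"):
        signals.detect_spikes(x, FS)


def test_mad_conventions():
    x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
    assert signals.robust_sigma(x, "divide") == pytest.approx(1.0 / 0.6745)
    assert signals.robust_sigma(x, "multiply") == pytest.approx(0.6745)
    with pytest.raises(ValueError):
        signals.robust_sigma(x, "other")


def test_false_positive_rate_on_noise_matches_brute_force_oracle(rng):
    """Detector event rate on pure Gaussian noise agrees with an independent
    step-by-step implementation of the crossing/dead-time rules (factor 2)."""
    x = rng.standard_normal(int(20 * FS))  # 20 s
    times = signals.detect_spikes(x, FS, k=3.5)

    thr = 3.5 * np.median(np.abs(x)) / 0.6745
    dead = int(round(1.5e-3 * FS))
    above = np.abs(x) >= thr
    n_oracle = 0
    i = 1
    while i < x.size:
        if above[i] and not above[i - 1]:
            n_oracle += 1
            i += dead
        else:
            i += 1
    assert n_oracle > 10
    assert 0.5 < times.size / n_oracle < 2.0


# ---------------------------------------------------------------------------
# spike-density function


def test_sdf_empty_train_is_zero():
    centers, sdf = signals.spike_density(np.empty(0), 0.0, 500.0)
    np.testing.assert_allclose(sdf, 0.0)
    assert np.all(np.diff(centers) > 0)


def test_sdf_single_spike_integrates_to_one():
    centers, sdf = signals.spike_density(np.array([250.0]), 0.0, 500.0)
    integral = sdf.sum() * (centers[1] - centers[0]) / 1000.0
    assert integral == pytest.approx(1.0, rel=1e-9)


def test_sdf_homogeneous_poisson_rate_recovered(rng):
    rate, n_trials, dur = 50.0, 100, 1000.0
    acc = None
    for _ in range(n_trials):
        n = rng.poisson(rate * dur / 1000.0)
        st = np.sort(rng.uniform(0, dur, n))
        centers, sdf = signals.spike_density(st, 0.0, dur)
        acc = sdf if acc is None else acc + sdf
    mean_sdf = acc / n_trials
    steady = mean_sdf[30:-30].mean()
    se = np.sqrt(rate * 1000.0 / (dur * n_trials))  # Poisson SE of the mean rate
    assert abs(steady - rate) < 3 * se


def test_sdf_kernel_unit_sum():
    k = signals.sdf_kernel()
    assert k.sum() == pytest.approx(1.0)
    assert k.size % 2 == 1


# ---------------------------------------------------------------------------
# pipeline properties


def test_envelope_linearity_under_input_scaling(rng):
    x = rng.standard_normal((1, 1, int(FS)))
    rec1 = WidebandRecording(x, FS, 0.0)
    rec2 = WidebandRecording(3.0 * x, FS, 0.0)
    e1, _ = signals.derive_mua_envelope(rec1)
    e2, _ = signals.derive_mua_envelope(rec2)
    np.testing.assert_allclose(e2, 3.0 * e1, rtol=1e-9)


def test_normalize_mua_schemes(rng):
    t = np.arange(-200.0, 500.0, 1.0)
    base = 5.0
    n_trials = 40
    traces = np.full((n_trials, t.size), base) + rng.normal(0, 1e-3, (n_trials, t.size))
    traces[:, (t >= 40) & (t < 140)] += 12.0
    conds = np.array(["A", "B"] * (n_trials // 2))
    norm, info = signals.normalize_mua(traces, t, "max_across_conditions",
                                       conditions=conds)
    assert norm[:, (t >= 40) & (t < 140)].mean(axis=0).max() == pytest.approx(1.0, rel=1e-2)
    assert info["denominator"] > 0
    # constant trace equal to its baseline -> all zeros under grand_mean_max
    with pytest.raises(ValueError, match="denominator"):
        signals.normalize_mua(np.full((4, t.size), 2.0), t, "grand_mean_max")


def test_normalize_rf_map_best_location_window_mean_is_one(rng):
    t = np.arange(-200.0, 500.0, 1.0)
    traces = rng.normal(0, 1e-6, (30, t.size))
    conds = np.repeat(["loc0", "loc1", "loc2"], 10)
    traces[conds == "loc1"][:, :] += 0.0
    boost = (t >= 50) & (t < 300)
    traces[10:20, boost] += 4.0   # loc1 strongest
    norm, info = signals.normalize_mua(traces, t, "rf_map", conditions=conds)
    best_mean = norm[10:20][:, boost].mean()
    assert best_mean == pytest.approx(1.0, rel=1e-3)
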