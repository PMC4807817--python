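"""End-to-end analysis pipelines: simulate (or load) -> derive -> fit -> stats.

`run_report` executes the full chain for one experiment kind and returns a
JSON-serializable bundle whose header records every parameter and seed, so
identical config + seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from . import context as ctx
from . import eyes, rf, signals, spectral, tuning
from .io import DEFAULT_CONFIG
from .synthetic import GroundTruth, NoiseConfig, make_design, simulate_session
from .types import SyntheticDataset


def _input_hash(dataset: SyntheticDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.recording.samples).tobytes())
    return h.hexdigest()[:16]


def simulate_for_config(cfg: dict) -> SyntheticDataset:
    noise = NoiseConfig(sampling_rate=float(cfg.get("sampling_rate", 32500.0)))
    truth = GroundTruth(seed=int(cfg.get("seed", 0)))
    design = make_design(cfg["experiment"], **cfg.get("design", {}))
    return simulate_session(truth, design, noise)


def _derive(dataset: SyntheticDataset, cfg: dict):
    k = float(cfg.get("k_threshold", 3.5))
    if cfg["experiment"] == "size":
        k = float(cfg.get("k_threshold_size", 4.0))
    return signals.derive_signals(dataset.recording, k=k,
                                  mad_convention=cfg.get("mad_convention", "divide"))


def _validate_windows(cfg: dict, times_ms: np.ndarray) -> None:
    for key in ("stim_window", "base_window", "early_window", "late_window"):
        lo, hi = cfg[key]
        if lo < times_ms[0] or hi > times_ms[-1] + 1.0:
            raise ValueError(f"{key} {cfg[key]} lies outside the trial range")


def run_report(cfg: dict, dataset: SyntheticDataset | None = None) -> dict:
    """Run the configured experiment's pipeline and return the report bundle."""
    cfg = {**DEFAULT_CONFIG, **cfg}
    if dataset is None:
        dataset = simulate_for_config(cfg)
    derived = _derive(dataset, cfg)
    t = derived.times_ms
    _validate_windows(cfg, t)
    mua = derived.mua_envelope[:, 0, :]
    lfp = derived.lfp[:, 0, :]
    stim = dataset.stimuli
    exp = cfg["experiment"]

    report = {
        "header": {
            "experiment": exp,
            "seed": int(cfg["seed"]),
            "config": {k: v for k, v in sorted(cfg.items()) if k != "design"},
            "input_hash": _input_hash(dataset),
            "n_trials": int(dataset.recording.n_trials),
        }
    }

    if exp == "rf":
        norm, info = signals.normalize_mua(mua, t, "rf_map",
                                           conditions=stim["condition"])
        rmap = rf.build_response_map(norm, t, stim, signal_kind="mua")
        fit = rf.fit_rf_gaussian(rmap)
        center = (fit.rf_x, fit.rf_y) if fit.converged else dataset.truth.rf_center
        near, far = rf.split_near_far(stim, center)
        latency = rf.response_latency(norm[near], norm[far], t)
        gmap = spectral.gamma_response_map(lfp, t, derived.sampling_rate, stim)
        gfit = rf.fit_rf_gaussian(gmap)
        report["rf"] = {"mua_fit": dataclasses.asdict(fit),
                        "gamma_fit": dataclasses.asdict(gfit),
                        "latency_ms": latency,
                        "normalization": info}
    elif exp == "orientation":
        norm, info = signals.normalize_mua(mua, t, cfg["normalization"],
                                           conditions=stim["condition"])
        resp = tuning.window_mean_responses(norm, t)
        ori_rad = np.deg2rad(stim["orientation"].to_numpy())
        angles, means = tuning.condition_means(resp, ori_rad)
        cv = tuning.circular_variance_tuning(means, angles)
        p = tuning.bootstrap_tuning_p(resp, ori_rad, n_boot=int(cfg["n_boot"]),
                                      seed=int(cfg["seed"]))
        fit = tuning.fit_orientation_gaussian(means, np.rad2deg(angles))
        fit.one_minus_circvar, fit.p_boot = cv, p
        dir_rad = np.deg2rad(stim["direction"].to_numpy())
        d_angles, d_means = tuning.condition_means(resp, dir_rad)
        cv_dir = tuning.circular_variance_tuning(d_means, d_angles, mode="direction")
        gr = spectral.band_power_ratio(lfp, t, derived.sampling_rate,
                                       band=tuple(cfg["gamma_band"]),
                                       stim_window=tuple(cfg["stim_window"]),
                                       base_window=tuple(cfg["base_window"]),
                                       conditions=stim["orientation"])
        g_ori = np.deg2rad(np.array(sorted(gr)))
        g_resp = np.array([gr[k] - 1.0 for k in sorted(gr)])
        cv_gamma = tuning.circular_variance_tuning(np.clip(g_resp, 0, None), g_ori)
        f, rel = spectral.relative_spectrum(lfp, t, derived.sampling_rate,
                                            tuple(cfg["stim_window"]),
                                            tuple(cfg["base_window"]))
        gpeak = spectral.fit_gamma_peak(f, rel, tuple(cfg["gamma_band"]))
        report["orientation"] = {
            "fit": dataclasses.asdict(fit),
            "one_minus_circvar": cv, "p_boot": p,
            "one_minus_circvar_direction": cv_dir,
            "one_minus_circvar_gamma": cv_gamma,
            "gamma_peak": dataclasses.asdict(gpeak),
            "normalization": info,
        }
    elif exp == "contrast":
        norm, info = signals.normalize_mua(mua, t, cfg["normalization"],
                                           conditions=stim["condition"])
        resp = tuning.window_mean_responses(norm, t)
        cs, means = tuning.condition_means(resp, stim["contrast"].to_numpy())
        fit = tuning.fit_naka_rushton(means, cs)
        report["contrast"] = {"fit": dataclasses.asdict(fit),
                              "contrasts": cs, "mean_responses": means,
                              "normalization": info}
    elif exp == "size":
        norm, info = signals.normalize_mua(mua, t, cfg["normalization"],
                                           conditions=stim["condition"])
        resp = tuning.window_mean_responses(norm, t)
        ss, means = tuning.condition_means(resp, stim["diameter"].to_numpy())
        fit = tuning.fit_rog_size(means, ss)
        report["size"] = {"fit": dataclasses.asdict(fit),
                          "sizes": ss, "mean_responses": means,
                          "normalization": info}
    elif exp == "context":
        norm, info = signals.normalize_mua(mua, t, "center_only_max",
                                           conditions=stim["condition"])
        conds = stim["condition"].to_numpy()
        traces = {c: norm[conds == c] for c in np.unique(conds)}
        otss, fgm = ctx.contextual_modulation(traces, t,
                                              early=tuple(cfg["early_window"]),
                                              late=tuple(cfg["late_window"]))
        report["context"] = {"otss": _mod_dict(otss), "fgm": _mod_dict(fgm),
                             "normalization": info}
    elif exp == "tracing":
        correct = stim["correct"].to_numpy().astype(bool)
        keep_fix = eyes.fixation_filter(np.flatnonzero(correct), dataset.eye,
                                        radius_deg=float(cfg["fix_radius"]))
        no_ms = eyes.reject_microsaccade_trials(dataset.eye,
                                               vthresh=float(cfg["vthresh"]),
                                               min_dur_ms=float(cfg["min_dur_ms"]))
        keep = np.intersect1d(keep_fix, no_ms)
        norm, info = signals.normalize_mua(mua[keep], t, "grand_mean_max")
        conds = stim["condition"].to_numpy()[keep]
        traces = {c: norm[conds == c] for c in np.unique(conds)}
        att = ctx.attention_modulation(traces, t)
        stats = eyes.eye_condition_stats(dataset.eye, stim["condition"],
                                         "Target", ("DistractorNear", "DistractorFar"))
        report["tracing"] = {"attention": dataclasses.asdict(att),
                             "n_kept_trials": int(keep.size),
                             "eye_stats": stats, "normalization": info}
    else:
        raise ValueError(f"unknown experiment type {exp!r}")
    return report


def _mod_dict(m) -> dict:
    d = dataclasses.asdict(m)
    d.pop("timecourse")
    d.pop("times_ms")
    return d
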