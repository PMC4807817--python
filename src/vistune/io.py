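"""Session container I/O and configuration.

A session lives in one HDF5 file with groups ``/wideband``, ``/stimuli``,
``/eye``, ``/truth`` and (after derivation) ``/derived``.  Stimulus tables
round-trip through the container bit-exactly and can also be exported as
CSV.  Configuration is a flat YAML mapping of analysis parameters with the
standard defaults pre-filled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (DerivedSignals, EyeTrace, GroundTruth, SyntheticDataset,
                    WidebandRecording)

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a container is missing required groups or mismatches the schema."""


DEFAULT_CONFIG = {
    "experiment": "orientation",
    "seed": 0,
    "sampling_rate": 32500.0,
    "k_threshold": 3.5,           # 4.0 for size-tuning sessions
    "mad_convention": "divide",
    "n_boot": 10000,
    "vthresh": 10.0,
    "min_dur_ms": 10.0,
    "fix_radius": 1.0,
    "gamma_band": [30.0, 100.0],
    "stim_window": [150.0, 450.0],
    "base_window": [-300.0, 0.0],
    "early_window": [50.0, 100.0],
    "late_window": [100.0, 500.0],
    "normalization": "max_across_conditions",
}


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    cfg.update(overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _write_table(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object or data.dtype.kind in "US":
            data = np.asarray([str(v) for v in data], dtype=h5py.string_dtype())
        group.create_dataset(col, data=data)
    group.attrs["columns"] = json.dumps(list(df.columns))


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    out = {}
    for col in cols:
        data = group[col][...]
        if data.dtype.kind in ("O", "S"):
            data = np.asarray([v.decode() if isinstance(v, bytes) else v for v in data])
        out[col] = data
    return pd.DataFrame(out)


def write_session(path, dataset: SyntheticDataset) -> None:
    """Write a simulated session (wideband + stimuli + eye + truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        g = fh.create_group("wideband")
        g.create_dataset("samples", data=dataset.recording.samples)
        g.attrs["sampling_rate"] = dataset.recording.sampling_rate
        g.attrs["t0_offset_ms"] = dataset.recording.t0_offset_ms
        g.attrs["channel_ids"] = json.dumps(list(dataset.recording.channel_ids))
        _write_table(fh.create_group("stimuli"), dataset.stimuli)
        e = fh.create_group("eye")
        e.create_dataset("x", data=dataset.eye.x)
        e.create_dataset("y", data=dataset.eye.y)
        e.attrs["sampling_rate"] = dataset.eye.sampling_rate
        e.attrs["t0_offset_ms"] = dataset.eye.t0_offset_ms
        t = fh.create_group("truth")
        t.attrs["json"] = json.dumps(dataclasses.asdict(dataset.truth), default=list)


def read_session(path) -> SyntheticDataset:
    """Read a session container; write-then-read reproduces arrays bit-exactly."""
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError("schema version mismatch")
        for grp in ("wideband", "stimuli", "eye", "truth"):
            if grp not in fh:
                raise SchemaError(f"missing /{grp} group")
        g = fh["wideband"]
        rec = WidebandRecording(g["samples"][...], float(g.attrs["sampling_rate"]),
                                float(g.attrs["t0_offset_ms"]),
                                json.loads(g.attrs["channel_ids"]))
        stim = _read_table(fh["stimuli"])
        e = fh["eye"]
        eye = EyeTrace(e["x"][...], e["y"][...], float(e.attrs["sampling_rate"]),
                       float(e.attrs["t0_offset_ms"]))
        td = json.loads(fh["truth"].attrs["json"])
        for key in ("rf_center", "rog_params"):
            td[key] = tuple(td[key])
        if td.get("modulation"):
            td["modulation"] = {k: [tuple(p) for p in v]
                                for k, v in td["modulation"].items()}
        truth = GroundTruth(**td)
    return SyntheticDataset(rec, stim, eye, truth)


def write_derived(path, derived: DerivedSignals) -> None:
    """Store derived signals under /derived in an existing session container."""
    with h5py.File(path, "a") as fh:
        if "derived" in fh:
            del fh["derived"]
        g = fh.create_group("derived")
        g.create_dataset("lfp", data=derived.lfp)
        g.create_dataset("mua_envelope", data=derived.mua_envelope)
        g.create_dataset("sdf", data=derived.sdf)
        g.create_dataset("sdf_times_ms", data=derived.sdf_times_ms)
        g.attrs["sampling_rate"] = derived.sampling_rate
        g.attrs["t0_offset_ms"] = derived.t0_offset_ms
        g.attrs["channel_ids"] = json.dumps(list(derived.channel_ids))
        st = g.create_group("spike_times")
        for tr, chans in enumerate(derived.spike_times):
            for ch, times in enumerate(chans):
                st.create_dataset(f"t{tr}_c{ch}", data=np.asarray(times))
        st.attrs["n_trials"] = len(derived.spike_times)
        st.attrs["n_channels"] = len(derived.spike_times[0]) if derived.spike_times else 0


def read_derived(path) -> DerivedSignals:
    with h5py.File(path, "r") as fh:
        if "derived" not in fh:
            raise SchemaError("missing /derived group")
        g = fh["derived"]
        st = g["spike_times"]
        spikes = [[st[f"t{tr}_c{ch}"][...] for ch in range(st.attrs["n_channels"])]
                  for tr in range(st.attrs["n_trials"])]
        return DerivedSignals(g["lfp"][...], g["mua_envelope"][...], spikes,
                              g["sdf"][...], float(g.attrs["sampling_rate"]),
                              float(g.attrs["t0_offset_ms"]),
                              sdf_times_ms=g["sdf_times_ms"][...],
                              channel_ids=json.loads(g.attrs["channel_ids"]))


def export_stimulus_csv(dataset: SyntheticDataset, path) -> None:
    dataset.stimuli.to_csv(path, index=False)


def dump_report(report: dict, path) -> None:
    """Deterministic JSON dump (sorted keys, fixed float handling)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2,
                                     default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
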