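"""Shared fixtures: small synthetic sessions reused across test modules.

Simulations run at 12.5 kHz (well above the 2 x 5 kHz spike-band minimum)
to keep the suite fast; the science is unchanged.
"""

import numpy as np
import pytest

from vistune import signals
from vistune import synthetic as syn

FAST_FS = 12500.0


@pytest.fixture(scope="session")
def fast_noise():
    return syn.NoiseConfig(sampling_rate=FAST_FS)


@pytest.fixture(scope="session")
def orientation_session(fast_noise):
    """10 repeats x 24 directions with the default ground truth (seed 3)."""
    truth = syn.GroundTruth(seed=3)
    ds = syn.simulate_session(truth, syn.orientation_design(repeats=10), fast_noise)
    derived = signals.derive_signals(ds.recording)
    return ds, derived


@pytest.fixture(scope="session")
def rf_session(fast_noise):
    """Full 11 x 11 mapping grid, 5 repeats per location (seed 7)."""
    truth = syn.GroundTruth(seed=7)
    ds = syn.simulate_rf_grid(truth, {"repeats": 5}, fast_noise)
    derived = signals.derive_signals(ds.recording)
    return ds, derived


@pytest.fixture(scope="session")
def context_session(fast_noise):
    truth = syn.GroundTruth(seed=11)
    ds = syn.simulate_session(truth, syn.context_design(repeats=80), fast_noise)
    derived = signals.derive_signals(ds.recording)
    return ds, derived


@pytest.fixture(scope="session")
def tracing_session(fast_noise):
    truth = syn.GroundTruth(seed=502)
    ds = syn.simulate_session(truth, syn.tracing_design(repeats=45), fast_noise)
    derived = signals.derive_signals(ds.recording)
    return ds, derived


def normalized_mua(ds, derived, scheme="max_across_conditions"):
    norm, info = signals.normalize_mua(
        derived.mua_envelope[:, 0, :], derived.times_ms, scheme,
        conditions=ds.stimuli["condition"])
    return norm, info


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
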