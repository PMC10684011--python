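"""Shared fixtures: synthetic sessions generated once per test run."""

import numpy as np
import pytest

from cardiomotor import cardiac
from cardiomotor.synthgen import SynthConfig, gen_pinch_task, gen_session


def effects_on_config(**overrides) -> SynthConfig:
    """A scaled-down session with every phase effect switched on."""
    base = dict(
        seed=11, rate=1000.0, n_tms=60, n_sham=60, n_pinch=12,
        mep_systole_gain=1.3, mep_distance_slope=4e-4,
        tep_systole_gain=1.5, hep_mep_coupling=1.0,
        erd_depth=0.3, erd_systole_gain=1.3,
        ibi_decel_ms=40.0, ibi_accel_ms=30.0,
    )
    base.update(overrides)
    return SynthConfig(**base)


def null_config(**overrides) -> SynthConfig:
    """Same scale with every effect at its null value."""
    nulls = dict(
        mep_systole_gain=1.0, mep_distance_slope=0.0, tep_systole_gain=1.0,
        hep_mep_coupling=0.0, erd_depth=0.0, erd_systole_gain=1.0,
        ibi_decel_ms=0.0, ibi_accel_ms=0.0)
    nulls.update(overrides)
    return effects_on_config(**nulls)


@pytest.fixture(scope="session")
def session_effects():
    """Effects-on session plus the full ECG detection chain."""
    cfg = effects_on_config()
    rec, events, truth = gen_session(cfg)
    ecg = cardiac.interpolate_stim_artifact_ecg(
        rec.channel("ECG"), rec.rate, events.times)
    r = cardiac.detect_r_peaks(ecg, rec.rate)
    te = cardiac.detect_t_end(ecg, r, rec.rate)
    cmap = cardiac.build_cardiac_map(r, te)
    classified = cardiac.classify_events(events, cmap)
    return {"cfg": cfg, "rec": rec, "events": events, "truth": truth,
            "ecg": ecg, "r": r, "t_end": te, "cmap": cmap,
            "classified": classified}


@pytest.fixture(scope="session")
def pinch_effects():
    cfg = effects_on_config(seed=12)
    rec, events, truth = gen_pinch_task(cfg)
    return {"cfg": cfg, "rec": rec, "events": events, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
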