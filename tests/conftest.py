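"""Shared fixtures: presets and simulated records reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fosubstep.analyze import DetectionParams, analyze_trace
from fosubstep.presets import get_preset
from fosubstep.simulate import (
    KineticConfig,
    OpticsConfig,
    sample_rotor_trajectory,
    trajectory_to_intensity,
)


@pytest.fixture(scope="session")
def wt_td_model():
    return get_preset("WT").td_model


@pytest.fixture(scope="session")
def wt_synthase_model():
    return get_preset("WT").synthase_model


@pytest.fixture(scope="session")
def wt_kinetics():
    return KineticConfig.from_preset("WT")


@pytest.fixture(scope="session")
def default_optics():
    return OpticsConfig()


def _make_record(kinetics, optics, ph, duration, seed):
    traj = sample_rotor_trajectory(kinetics, ph=ph, duration=duration, seed=seed)
    trace = trajectory_to_intensity(traj, optics, seed=seed + 1000)
    return traj, trace


@pytest.fixture(scope="session")
def noisy_cohort(wt_kinetics, default_optics):
    """Five 6-s WT records at pH 5.5 with default noise, fully analyzed.

    Low pH makes most power strokes carry 2-3 transient dwells, giving
    ~1000 within-stroke spacing pairs pooled across the cohort.
    """
    out = []
    for seed in (1, 7, 13, 21, 34):
        traj, trace = _make_record(wt_kinetics, default_optics, ph=5.5, duration=6.0, seed=seed)
        segments, events, summary = analyze_trace(trace, DetectionParams())
        out.append({"traj": traj, "trace": trace, "segments": segments,
                    "events": events, "summary": summary})
    return out


@pytest.fixture(scope="session")
def quiet_record(wt_kinetics):
    """One noise-free 4-s WT record at pH 5.5, analyzed."""
    optics = OpticsConfig(noise_sd=0.0)
    traj, trace = _make_record(wt_kinetics, optics, ph=5.5, duration=4.0, seed=3)
    segments, events, summary = analyze_trace(trace, DetectionParams())
    return {"traj": traj, "trace": trace, "segments": segments,
            "events": events, "summary": summary, "optics": optics}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
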