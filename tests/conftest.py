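"""Shared fixtures: small synthetic sessions, preprocessed signals."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from earbci.preprocess import preprocess_recording
from earbci.simulate import (
    ArtifactParams,
    NoiseParams,
    SignalModel,
    build_schedule,
    synthesize_recording,
)

FS = 250.0


@pytest.fixture(scope="session")
def hand_schedule():
    """Full-size hand-only session layout: 4 blocks x 25 trials."""
    return build_schedule(conditions=("hand",))


@pytest.fixture(scope="session")
def small_schedule():
    """Quick layout: 1 hand block of 10 trials."""
    return build_schedule(blocks_per_condition=1, trials_per_block=10,
                          conditions=("hand",))


@pytest.fixture(scope="session")
def clean_model():
    """Default signal model without artifacts (deterministic epoch content)."""
    return dataclasses.replace(SignalModel(), artifacts=ArtifactParams(rate=0.0))


@pytest.fixture(scope="session")
def noise_free_model():
    """No stochastic terms at all: recording = MRCP + modulated oscillation."""
    base = SignalModel()
    return dataclasses.replace(
        base,
        noise=NoiseParams(pink_sd=0.0, white_sd=0.0, line_amplitude=0.0),
        artifacts=ArtifactParams(rate=0.0),
        emg=dataclasses.replace(base.emg, baseline_sd=0.0),
    )


@pytest.fixture(scope="session")
def hand_session(hand_schedule, clean_model):
    """100-trial hand session plus ground truth (seeded)."""
    return synthesize_recording(hand_schedule, clean_model, seed=101)


@pytest.fixture(scope="session")
def hand_preprocessed(hand_session):
    rec, _ = hand_session
    return preprocess_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
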