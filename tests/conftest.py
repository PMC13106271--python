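"""Shared fixtures: seeded synthetic physiology at the study conditions."""

import numpy as np
import pytest

import camhrv
from camhrv.config import SessionConfig
from camhrv.synthetic import MILD_NOISE


@pytest.fixture(scope="session")
def truth():
    """Default 60 s beat series (75 BPM, LF+HF modulation, jitter)."""
    return camhrv.generate_rr(seed=11)


@pytest.fixture(scope="session")
def clean_rgb(truth):
    """Noise-free green-dominant RGB trace for the default truth."""
    return camhrv.generate_rgb(truth, noise=None, seed=12)


@pytest.fixture(scope="session")
def mild_rgb(truth):
    return camhrv.generate_rgb(truth, noise=MILD_NOISE, seed=13)


@pytest.fixture(scope="session")
def clean_ecg(truth):
    return camhrv.generate_ecg(truth, noise_sd=0.0)


@pytest.fixture()
def config3():
    return SessionConfig(pipeline_id=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
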