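"""Shared fixtures: seeded synthetic recordings at desk scale."""

import numpy as np
import pytest

from esgkit import SimParams, generate
from esgkit.preprocess import preprocess_uncleaned


@pytest.fixture(scope="session")
def sim60():
    """60-s default-montage simulation (35 channels) with ground truth."""
    return generate(SimParams(duration=60.0, seed=11))


@pytest.fixture(scope="session")
def uncleaned60(sim60):
    rec, _ = sim60
    return preprocess_uncleaned(rec)


@pytest.fixture(scope="session")
def small_sim():
    """Small montage (5 channels/patch) for the more expensive decompositions."""
    return generate(SimParams(n_channels_per_patch=5, duration=60.0, seed=7))


@pytest.fixture(scope="session")
def small_uncleaned(small_sim):
    rec, _ = small_sim
    return preprocess_uncleaned(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
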