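"""Shared fixtures: synthetic walking segments and tiny pose files."""

from __future__ import annotations

import numpy as np
import pytest

from gaitmono import GaitParams, PoseSequence, generate_gait


@pytest.fixture(scope="session")
def noiseless():
    """Healthy-preset segment with zero pose noise, plus its ground truth."""
    return generate_gait(GaitParams(noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy():
    """Healthy-preset segment at the default 3 mm pose noise."""
    return generate_gait(GaitParams(seed=2))


@pytest.fixture()
def tiny_seq():
    """Minimal 2-frame, 6-joint sequence with distinct coordinates."""
    coords = np.arange(2 * 6 * 3, dtype=float).reshape(2, 6, 3)
    return PoseSequence(coords=coords, fs=30.0).validate()
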