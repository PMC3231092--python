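import dataclasses

import numpy as np
import pytest

from cawall import (
    PhantomConfig,
    SubintimaNoiseSpec,
    default_roi,
    generate_sequence,
    systolic_frames,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def static_phantom():
    """Small noise-free, motion-free phantom (10 frames)."""
    cfg = PhantomConfig(
        n_frames=10, speckle_scale=0.0, pulsation_amplitude=0.0,
        wall_drift_amplitude=0.0, seed=5,
    )
    seq, truth = generate_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def pulsatile_phantom():
    """Noise-free pulsatile phantom with bulk drift (10 frames)."""
    cfg = PhantomConfig(
        n_frames=10, speckle_scale=0.0, pulsation_amplitude=4.0,
        frames_per_cycle=40, wall_drift_amplitude=1.0, seed=6,
    )
    seq, truth = generate_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def speckle_phantom():
    """Moderate-speckle pulsatile phantom with a systolic sub-intima layer."""
    cfg = PhantomConfig(n_frames=12, frames_per_cycle=40, seed=11)
    cfg = dataclasses.replace(
        cfg, subintima_noise=SubintimaNoiseSpec(frames=systolic_frames(cfg))
    )
    seq, truth = generate_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def lumen_roi(pulsatile_phantom):
    _, _, truth = pulsatile_phantom
    return default_roi(truth, "lumen")
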