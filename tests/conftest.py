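"""Shared fixtures: small low-rank synthetic worlds for the regression tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from mocapfill import (
    MotionSample,
    SkeletonModel,
    SynthConfig,
    generate_motion,
    make_training_windows,
)


@dataclass
class World:
    """Training windows + test window cut from one low-rank sequence."""

    training: list[MotionSample]
    test: MotionSample
    skeleton: SkeletonModel
    rank: int
    window: int


def _make_world(
    seed: int = 0,
    n_markers: int = 8,
    window: int = 120,
    n_train: int = 5,
    rank: int = 4,
    noise_sd: float = 0.0,
    burst=None,
) -> World:
    cfg = SynthConfig(
        n_markers=n_markers,
        m_frames=window * (n_train + 1),
        latent_rank=rank,
        noise_sd=noise_sd,
        seed=seed,
        burst=burst,
    )
    seq, skeleton = generate_motion(cfg)
    wins = make_training_windows(seq, window=window)
    return World(training=wins[:-1], test=wins[-1], skeleton=skeleton, rank=rank, window=window)


@pytest.fixture
def make_world():
    """Factory for low-rank worlds; test and training share the loading matrix."""
    return _make_world


@pytest.fixture
def world(make_world) -> World:
    """Default noiseless world: 8 markers, 5 x 120-frame training windows, rank 4."""
    return make_world()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
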