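"""Shared fixtures: small seeded synthetic subjects and helper constructors.

Heavy fixtures (a generated + preprocessed subject) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from boldmvpa.core import BoldRun, MotionParams, VoxelGrid
from boldmvpa.pipeline import ExperimentConfig, _preprocess_subject
from boldmvpa.simulate import SimConfig, generate_subject

SMALL_GRID = (16, 16, 16)
SMALL_N_SIGNAL = 320  # ~25% of the small phantom's GM


def make_run(
    data: np.ndarray,
    grid: VoxelGrid,
    condition: str = "trauma",
    repetition: int = 1,
    motion: np.ndarray | None = None,
    tr: float = 2.0,
) -> BoldRun:
    T = data.shape[3]
    motion = motion if motion is not None else np.zeros((T, 6))
    return BoldRun(
        data=data, grid=grid, tr_seconds=tr, condition=condition,
        repetition=repetition, motion=MotionParams(motion),
    )


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid.centered(SMALL_GRID)


@pytest.fixture(scope="session")
def signal_subject():
    """A small subject with strong stationary distributed signal + truth."""
    cfg = SimConfig(
        seed=11, effect_size=1.5, grid_dims=SMALL_GRID,
        n_signal_voxels=SMALL_N_SIGNAL,
    )
    return generate_subject(cfg)


@pytest.fixture(scope="session")
def preprocessed_subject(signal_subject):
    """The signal subject through the default (unsmoothed) pipeline."""
    ds, truth = signal_subject
    prep = _preprocess_subject(ds, ExperimentConfig(), smoothed=False)
    return prep, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
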