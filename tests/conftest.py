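"""Shared fixtures: small synthetic studies generated at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fairdecode.simulate import SimConfig, generate_pattern_study, generate_study


SMALL_GRID = (12, 12, 12)
VOXEL_MM = (3.5, 3.5, 3.5)


@pytest.fixture(scope="session")
def pattern_study():
    """31-subject pattern-level study with planted, behavior-linked signal."""
    return generate_pattern_study(SimConfig(seed=101, grid_shape=SMALL_GRID))


@pytest.fixture(scope="session")
def null_pattern_study():
    """Same design with zero planted amplitude: pure noise patterns."""
    return generate_pattern_study(
        SimConfig(seed=202, grid_shape=SMALL_GRID, signal_amplitude_max=0.0))


@pytest.fixture(scope="session")
def bold_study():
    """Tiny BOLD-level study (3 subjects) for end-to-end GLM tests."""
    return generate_study(SimConfig(seed=303, n_subjects=3, cohort_sizes=(2, 1),
                                    grid_shape=SMALL_GRID,
                                    selfishness_range=(0.0, 1.0)))


@pytest.fixture()
def simple_events():
    """Four well-spaced trials covering all cells."""
    return pd.DataFrame({
        "onset": [0.0, 22.0, 44.0, 66.0],
        "duration": [6.0] * 4,
        "game": ["UG", "DG", "UG", "DG"],
        "opponent": ["human", "human", "computer", "computer"],
        "response_time": [12.0, 34.0, 56.0, 78.0],
        "offer": [10.0, 4.0, 8.0, 2.0],
    })


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
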