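import numpy as np
import pytest

from rataffect import synthetic as syn
from rataffect import trajectories as tj


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def of_arena():
    return tj.OpenFieldArena()


@pytest.fixture
def epm_arena():
    return tj.EPMArena()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny reference cohort reused by pipeline-level tests."""
    design = syn.reference_design(effect_sd=1.5, n=4, seed=42, threshold_days=[0, 21])
    return syn.simulate_cohort(design)


def make_trajectory(times, xy, arena, duration=300.0):
    return tj.Trajectory(np.asarray(times, float), np.asarray(xy, float), arena, duration)
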