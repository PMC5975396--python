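"""Shared fixtures: small phantom cohorts and simple geometric objects."""

import numpy as np
import pytest

from shapeseg import LabelMask, Volume
from shapeseg.phantom import PhantomSpec, generate_cohort, split_train_test


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse, fast study conditions for unit tests (same world extent as the
    default cohort but 32^3 voxels at 4 mm)."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
                       n_vertices=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, 6, seed=7)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_train_test(small_cohort, 4, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """A few cases at the standard 64^3 / 2 mm conditions."""
    return generate_cohort(PhantomSpec(), 4, seed=11)


@pytest.fixture()
def ball_mask() -> LabelMask:
    """Digital ball of radius 10 voxels centered in a 32^3 grid (2 mm)."""
    n, r = 32, 10
    idx = np.indices((n, n, n))
    c = (n - 1) / 2
    ball = (((idx - c) ** 2).sum(0) <= r**2).astype(np.uint8)
    return LabelMask(ball, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
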