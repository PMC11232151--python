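import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from radioshrink.cohort import CohortConfig
from radioshrink.imaging import PreprocessConfig, VolumeImage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240701)


@pytest.fixture
def small_cfg():
    """A small but nontrivial cohort configuration for unit tests."""
    return CohortConfig(n_patients=40, seed=123)


@pytest.fixture
def preprocess_cfg():
    return PreprocessConfig(target_spacing_mm=1.2)


def random_levels(rng, shape, n_levels):
    """Random discretized region: levels 1..n_levels with an irregular mask."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    levels[~mask] = 0
    if levels.max() == 0:
        levels.flat[0] = 1
    return levels


def make_ellipsoid_volume(radii_vox, pad=4, value=200.0, background=10.0,
                          noise=0.0, rng=None):
    """Bright axis-aligned ellipsoid phantom on a dark background."""
    shape = tuple(int(2 * r + 2 * pad + 1) for r in radii_vox)
    center = np.array([(s - 1) / 2 for s in shape])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    mask = acc <= 1.0
    vol = np.full(shape, background)
    vol[mask] = value
    if noise > 0:
        vol = vol + rng.normal(0, noise, size=shape)
    return vol, mask
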