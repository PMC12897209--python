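import numpy as np
import pytest

from perfquant import PhantomConfig, generate_phantom

# a reduced grid keeps each phantom ~2k lung voxels; geometry is defined
# in relative units so all structural properties carry over
SMALL_GRID = (36, 26, 30)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def control_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture(scope="session")
def cteph_phantom(small_config):
    from dataclasses import replace

    cfg = replace(
        small_config, pattern="cteph_segmental", target_defect_fraction=0.30, n_wedges=3, seed=7
    )
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pair_and_masks(seed: int, shape=(8, 8, 8), max_count: int = 40):
    """Random SPECT volume with random (x-split) lung masks for oracle tests."""
    from perfquant import LungMasks, VolumePair

    r = np.random.default_rng(seed)
    spect = r.integers(1, max_count, size=shape).astype(float)
    ct = np.full(shape, -800.0)
    half = shape[0] // 2
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    left[half:] = r.random(size=(shape[0] - half, *shape[1:])) < 0.6
    right[:half] = r.random(size=(half, *shape[1:])) < 0.6
    if not left.any():
        left[half, 0, 0] = True
    if not right.any():
        right[0, 0, 0] = True
    pair = VolumePair(ct=ct, spect=spect, spacing_mm=(2.0, 2.0, 2.0))
    masks = LungMasks(left=left, right=right, spacing_mm=(2.0, 2.0, 2.0))
    return pair, masks
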