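import numpy as np
import pytest

import lungfv as lf


def make_study(values, spacing=2.0):
    """A tiny 1D-column study: one voxel per value, AV covering all voxels."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    grid = lf.ImageGrid((arr.shape[0], 1, 1), (spacing,) * 3)
    pet = lf.ScalarVolume(grid, arr)
    av = lf.BinaryMask(grid, np.ones(arr.shape, dtype=bool))
    return pet, av


@pytest.fixture
def four_voxel():
    """The hand-checked four-voxel study with AV activities {10, 5, 3, 2}."""
    return make_study([10.0, 5.0, 3.0, 2.0])


@pytest.fixture(scope="session")
def gradient_phantom():
    """A noisy linear-gradient phantom on a coarse grid (fast unit tests)."""
    spec = lf.PhantomSpec(
        grid=lf.default_grid(32, 8.0),
        activity_pattern=lf.LinearGradient(axis=2, ratio=3.0),
        noise_sigma_rel=0.12,
        seed=5,
    )
    return lf.generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64-cube uniform phantom (noiseless apart from tie jitter)."""
    return lf.generate_phantom(lf.PhantomSpec(seed=11))
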