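"""Shared fixtures: small, fast phantoms and default configurations."""

import numpy as np
import pytest

from mrfseg import ImageStack, PhantomSpec, VoxelSpacing, generate_phantom


def small_phantom_spec(seed: int) -> PhantomSpec:
    """A 4x64x64 phantom that keeps full-pipeline tests fast.

    Radii are scaled with the smaller field of view so objects still fit.
    """
    return PhantomSpec(shape=(4, 64, 64), organoid_radius_range=(6.0, 9.0),
                       strand_radius=2.0, strand_steps=40, seed=seed)


@pytest.fixture(scope="session")
def small_phantom():
    """One small two-channel phantom with ground truth (seed 0)."""
    return generate_phantom(small_phantom_spec(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_stack(rng):
    """A random two-channel 8-bit stack, no structure."""
    data = rng.integers(0, 256, size=(3, 24, 24, 2), dtype=np.uint8)
    return ImageStack(data, VoxelSpacing(10.0, 0.5, 0.5))
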