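import numpy as np
import pytest

from ctmorph.phantom import PhantomSpec, generate_fish_phantom, phantom_atlas


SMALL_SHAPE = (96, 64, 64)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-size phantom spec shared by the quicker tests."""
    return PhantomSpec(shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Noisy phantom + ground-truth labels (session-cached, treat as read-only)."""
    return generate_fish_phantom(small_spec, seed=101)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom + labels."""
    spec = PhantomSpec(shape=SMALL_SHAPE, noise_sd=0.0)
    return generate_fish_phantom(spec, seed=101)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    """Phantom atlas (clean reference + truth labels) at desk size."""
    return phantom_atlas(small_spec)


def digital_ball(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    c = (n - 1) / 2.0
    zz, yy, xx = np.indices((n, n, n))
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
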