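import numpy as np
import pytest

from axonseg import PhantomConfig, generate_phantom


class StubRng:
    """Deterministic stand-in for numpy Generator with scripted draws."""

    def __init__(self, randoms=(), uniforms=(), integers=()):
        self._randoms = list(randoms)
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def random(self, *a, **k):
        return self._randoms.pop(0)

    def uniform(self, low, high=None, size=None):
        v = self._uniforms.pop(0)
        if size is None:
            return v
        return np.broadcast_to(np.asarray(v, dtype=float), np.atleast_1d(size)).copy()

    def integers(self, *a, **k):
        return self._integers.pop(0)


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture(scope="session")
def small_phantom():
    """One small annotated cube: 48-voxel padded image, 32-voxel dense labels."""
    cfg = PhantomConfig(cube_edge=32, pad=8, n_tubes=4, seed=11)
    image, dense = generate_phantom(cfg)
    return cfg, image, dense


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
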