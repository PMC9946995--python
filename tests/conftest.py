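import numpy as np
import pytest

from rangeres import synthetic


@pytest.fixture
def tiny_config():
    """A small world for unit tests: 4x4 coarse pixels at block 7."""
    return synthetic.WorldConfig(grid_rows=28, grid_cols=28, rain_rows=2, rain_cols=2, seed=7)


@pytest.fixture
def tiny_world(tiny_config):
    return synthetic.generate_world(tiny_config, "loss_of_resistance")


@pytest.fixture
def flat_scene():
    """Uniform-band scene helper factory."""

    def make(blue, red, nir, swir, shape=(3, 3), date=2016.5, valid=None):
        full = lambda v: np.full(shape, float(v))
        from rangeres.spectral import Scene

        return Scene(date=date, blue=full(blue), red=full(red), nir=full(nir), swir=full(swir), valid=valid)

    return make
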