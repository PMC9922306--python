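import numpy as np
import pytest

from aoflio import AcquisitionMeta, build_mosaic, default_irf, render_cube

SMALL_FIELD = (80, 100)


@pytest.fixture(scope="session")
def meta():
    """Standard acquisition: 80 MHz, 256 bins, one full period."""
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def small_meta():
    return AcquisitionMeta(pixel_dims=SMALL_FIELD)


@pytest.fixture(scope="session")
def irf(meta):
    return default_irf(meta)


@pytest.fixture(scope="session")
def small_irf(small_meta):
    return default_irf(small_meta)


@pytest.fixture(scope="session")
def small_scene():
    """~50-cone mosaic on an 80x100 field, fast enough for per-test rendering."""
    return build_mosaic(field_dims=SMALL_FIELD, cone_spacing_px=12.0,
                        s_fraction=0.12, seed=11)


@pytest.fixture(scope="session")
def small_render(small_scene, small_irf, small_meta):
    cube, mask = render_cube(small_scene, small_irf, small_meta, seed=5)
    return cube, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
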