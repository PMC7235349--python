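import numpy as np
import pytest

from irsh.core_io import SpectralImage, Spectrum, WavenumberAxis
from irsh.phantom import PhantomConfig


@pytest.fixture
def acq_axis() -> WavenumberAxis:
    """Descending acquisition axis 4000 -> 750 cm^-1, 2 cm^-1 spacing."""
    return WavenumberAxis(np.arange(4000.0, 749.0, -2.0))


@pytest.fixture
def small_axis() -> WavenumberAxis:
    """Short descending axis for cheap fixtures."""
    return WavenumberAxis(np.arange(1800.0, 799.0, -10.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(small_axis, rng) -> SpectralImage:
    cube = rng.normal(0.5, 0.1, (5, 4, small_axis.n))
    mask = np.ones((5, 4), dtype=bool)
    mask[0, 0] = False
    return SpectralImage(
        small_axis, cube, mask=mask, meta={"sample_id": "img0", "group": "WT"}
    )


@pytest.fixture
def tiny_cfg() -> PhantomConfig:
    """Small, bulb-free phantom config for fast structural tests."""
    return PhantomConfig(rows=20, cols=12, n_hair_bulbs=0, seed=5)


def spectrum_on(axis: WavenumberAxis, values) -> Spectrum:
    return Spectrum(axis, np.asarray(values, dtype=float))
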