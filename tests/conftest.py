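import numpy as np
import pytest

from earlyflt import (FluorophoreProps, OpticalMedium, PhantomConfig,
                      ProbeGeometry, make_phantom)


@pytest.fixture
def medium():
    """Reference background medium of the digital phantom."""
    return OpticalMedium(mua=0.01, mus=2.63, g=0.62, n=1.521)


@pytest.fixture
def fluor():
    """Reference fluorophore: Cy5-like, γ = 0.2, τ = 900 ps."""
    return FluorophoreProps(muaf=0.01, gamma=0.2, tau=900.0)


@pytest.fixture
def probe():
    return ProbeGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_phantom():
    """Coarse phantom for fast Monte Carlo checks: 30×30×24 voxels of
    0.5 mm, cylinder of diameter 2 mm with its center 4.2 mm deep."""
    cfg = PhantomConfig(grid_shape=(30, 30, 24), voxel_size=0.5,
                        grid_origin=(-7.5, -7.5, 0.0))
    return make_phantom(cfg)
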