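import numpy as np
import pytest

from endothelix import MosaicParams, make_lattice, make_mosaic


@pytest.fixture(scope="session")
def square_lattice():
    return make_lattice("square", size_px=350, side_to_side_px=25)


@pytest.fixture(scope="session")
def hex_lattice():
    return make_lattice("hexagonal", size_px=350, side_to_side_px=25)


@pytest.fixture(scope="session")
def mosaic():
    """A 350x350 mosaic at typical clinical density with mild noise."""
    return make_mosaic(MosaicParams(rng_seed=1, shape=(350, 350)))


@pytest.fixture(scope="session")
def clean_mosaic():
    """A noise-free, evenly lit mosaic (easy segmentation target)."""
    return make_mosaic(
        MosaicParams(rng_seed=3, shape=(350, 350), noise_sd=0.0, illumination_gradient=0.0)
    )


@pytest.fixture(scope="session")
def true_f_star():
    """f* implied by the default mosaic density (cells/px^2 = f*^2 at alpha=1)."""
    p = MosaicParams()
    return float(np.sqrt(p.density_mm2 / (1000.0 / p.sampling_um_per_px) ** 2))
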