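import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from enfaceoct.synthetic_data import (
    PhantomParams,
    GaussianElevation,
    SRFPocket,
    VesselShadow,
    make_phantom,
)


def small_params(**kw) -> PhantomParams:
    """A quick desk phantom: 200×120×24 voxels, one dome, one SRF pocket,
    one vessel shadow; speckle off unless requested."""
    base = PhantomParams(
        dims=(200, 120, 24),
        elevations=(GaussianElevation(center=(40.0, 8.0), amplitude_px=10.0,
                                      sigma=(40.0, 8.0)),),
        srf_pockets=(SRFPocket(center=(80.0, 14.0), semi_axes=(25.0, 6.0),
                               height_px=24),),
        vessel_shadows=(VesselShadow(x_center=20, width_px=4),),
        speckle="off",
    )
    return base.with_(**kw)


@pytest.fixture
def noiseless_phantom():
    return make_phantom(small_params())


@pytest.fixture
def speckled_phantom():
    return make_phantom(small_params(speckle="gamma", seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
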