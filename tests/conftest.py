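import numpy as np
import pytest

from ottlsm import (OpticalConfig, bessel_gauss_field, make_sheet,
                    sheet_metrics)


@pytest.fixture(scope="session")
def default_cfg():
    return OpticalConfig()


@pytest.fixture(scope="session")
def bessel_field(default_cfg):
    return bessel_gauss_field(default_cfg)


@pytest.fixture(scope="session")
def sheet_2p(default_cfg, bessel_field):
    return make_sheet(bessel_field, 60.0, "two_photon", default_cfg.grid)


@pytest.fixture(scope="session")
def sheet_1p(default_cfg, bessel_field):
    return make_sheet(bessel_field, 60.0, "one_photon", default_cfg.grid)


@pytest.fixture(scope="session")
def sheet_2p_metrics(sheet_2p):
    return sheet_metrics(sheet_2p)


@pytest.fixture(scope="session")
def point_phantom():
    """Single bright voxel centred at world (Z, Y, X) = (20.25, 30.25, 50.25) um."""
    from ottlsm import Phantom
    fluor = np.zeros((80, 120, 160))
    fluor[40, 60, 100] = 1000.0
    return Phantom(fluor=fluor, shg=np.zeros_like(fluor),
                   voxel_pitch_um=(0.5, 0.5, 0.5))
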