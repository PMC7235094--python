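import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nanosyn import (
    ChannelImage,
    GroundTruthScene,
    NCTruth,
    PSDTruth,
    RenderSpec,
    SceneParams,
    generate_scene,
)
from nanosyn.core import sigma_to_fwhm


@pytest.fixture(scope="session")
def default_scene():
    """One seeded scene at the default study conditions."""
    return generate_scene(SceneParams(), seed=42)


@pytest.fixture()
def single_nc_scene():
    """Factory: a field holding one circular or elliptical NC."""

    def make(sigma_x_nm=60.0, sigma_y_nm=None, field_um=2.0, amplitude=1e5,
             centre=None, orientation=0.0, background=0.0):
        sigma_y_nm = sigma_x_nm if sigma_y_nm is None else sigma_y_nm
        centre = (field_um / 2, field_um / 2) if centre is None else centre
        short, long = sorted([sigma_to_fwhm(sigma_x_nm),
                              sigma_to_fwhm(sigma_y_nm)])
        nc = NCTruth(centre_um=centre, short_axis_nm=short, long_axis_nm=long,
                     orientation_rad=orientation, amplitude=amplitude)
        return GroundTruthScene(
            field_size_um=(field_um, field_um),
            psds=[PSDTruth(id=0, centre_um=centre, nc_list=[nc])],
            boutons=[],
            astro_domains=[],
            background_rate=background,
            seed=0,
        )

    return make


@pytest.fixture()
def noiseless_sted():
    """STED render spec without any noise source."""
    return RenderSpec.sted(poisson=False, read_noise_sd=0.0)


@pytest.fixture()
def flat_image():
    def make(value=5.0, shape=(64, 64), pixel_size_nm=100.0):
        return ChannelImage(np.full(shape, float(value)), pixel_size_nm)

    return make
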