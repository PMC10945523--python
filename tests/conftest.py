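import numpy as np
import pytest

from azphys.params import ImageSceneParams, PipelineParams
from azphys.sted_quant import quantify_field
from azphys.synth_imaging import render_sted_field


@pytest.fixture(scope="session")
def small_scene():
    """Compact field used throughout the imaging tests: one mossy-fiber
    bouton plus one sub-threshold terminal in a 5.12 um field."""
    return ImageSceneParams(field_px=512, n_terminals=1, n_small_terminals=1,
                            az_per_terminal_mean=8.0)


@pytest.fixture(scope="session")
def rendered_field(small_scene):
    return render_sted_field(small_scene, "WT", seed=1, field_id="f1",
                             animal_id="a1")


@pytest.fixture(scope="session")
def quantified_field(rendered_field):
    imgset, _ = rendered_field
    return quantify_field(imgset, PipelineParams())


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, PSF-free scene with a quiet Munc13-1 channel (bright
    pedestal, negligible cluster photons) for geometry-exact tests."""
    return ImageSceneParams(field_px=512, n_terminals=1, n_small_terminals=0,
                            az_per_terminal_mean=5.0, noise_model="none",
                            psf_fwhm_sted_nm=0.0, psf_fwhm_confocal_nm=0.0,
                            munc_pedestal=50.0, pedestal_taper_nm=0.0,
                            munc_cluster_intensity=1e-9)
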