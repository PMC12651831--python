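import numpy as np
import pytest

from bgrt.phantom import AcquisitionModel, PhantomSpec, build_phantom, simulate_scan
from bgrt.pipeline import StudyConfig, run_phantom_study


@pytest.fixture(scope="session")
def default_study():
    """The full 24-configuration phantom study under the default conditions."""
    return run_phantom_study(StudyConfig())


@pytest.fixture()
def sphere_image():
    """Factory for single-sphere phantom images on a compact grid."""

    def make(diameter_mm, tbr, grid_n=72, voxel_mm=1.0, background=5.0):
        spec = PhantomSpec(
            sphere_diameters_mm=[diameter_mm],
            background_kbq_ml=background,
            tbr=tbr,
            grid_shape=(grid_n,) * 3,
            voxel_mm=voxel_mm,
        )
        return build_phantom(spec)

    return make


@pytest.fixture()
def noisefree_model():
    return AcquisitionModel(psf_fwhm_mm=4.5, noise_cv=0.0)
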