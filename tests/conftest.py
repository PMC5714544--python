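import numpy as np
import pytest

from sbrt4d.beams import Beam
from sbrt4d.dose_engines import BeamModel, KernelSurrogate, RayTracingEPL
from sbrt4d.phantom4d import GridSpec, PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """Default-geometry phantom with a mid-size tumor and typical motion."""
    return PhantomConfig(gtv_volume_cc=10.2, amplitude_mm=12.0, n_phases=10)


@pytest.fixture(scope="session")
def small_study(small_phantom_config):
    return make_phantom(small_phantom_config, seed=123)


@pytest.fixture(scope="session")
def beam_model() -> BeamModel:
    return BeamModel.default()


@pytest.fixture()
def water_grid():
    """Water block with an air margin on every side, 2 mm voxels."""
    grid = GridSpec.centered((60, 60, 80), (2.0, 2.0, 2.0))
    x, y, z = grid.meshgrid()
    rho = np.zeros(grid.shape)
    rho[(np.abs(x) <= 50) & (np.abs(y) <= 50) & (z <= 61)] = 1.0
    return grid, rho


@pytest.fixture()
def axial_beam():
    """Beam along -z with the water surface (z=61) at 800-15 mm from source:
    the on-axis point at z=46 sits at dmax depth and at SAD."""
    return Beam(source=(0.0, 0.0, 846.0), direction=(0.0, 0.0, -1.0), aperture_radius_mm=25.0)


@pytest.fixture()
def fine_epl(beam_model):
    return RayTracingEPL(beam_model, step_w_mm=1.0, lateral_spacing_mm=2.0)


@pytest.fixture()
def fine_surrogate(beam_model):
    return KernelSurrogate(beam_model, step_w_mm=1.0, lateral_spacing_mm=2.0)
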