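import numpy as np
import pytest

from ocubeam import cnao
from ocubeam.beamline import default_range_model
from ocubeam.materials import beamline_materials, tissue_table


@pytest.fixture(scope="session")
def range_model():
    return default_range_model()


@pytest.fixture(scope="session")
def materials():
    return beamline_materials()


@pytest.fixture(scope="session")
def tissues():
    return tissue_table()


@pytest.fixture(scope="session")
def shifter_wet(range_model):
    """Degrader WET calibrated on the published 100.51 MeV residual range."""
    return float(range_model.range_mm(100.51)) - cnao.SOBP_LAYERS[0][1]


@pytest.fixture(scope="session")
def ten_layer_plan(range_model, shifter_wet):
    from ocubeam.delivery import build_sobp_plan, select_energy_layers

    layers = select_energy_layers(
        35.5, 18.0, 2.0, degrader_wet_mm=shifter_wet, range_model=range_model
    )
    return build_sobp_plan(layers, shifter_wet, range_model)


@pytest.fixture(scope="session")
def eye_grid():
    from ocubeam.eye import build_eye, voxelize

    return voxelize(build_eye(12.25, gaze_angle=40.0), 0.3, shape=(100, 100, 100))
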