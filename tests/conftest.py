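import numpy as np
import pytest

from dendratrack import imaging_analysis as ia
from dendratrack import photophysics as pp
from dendratrack import synthetic_data as sd


@pytest.fixture(scope="session")
def grid():
    return pp.WavelengthGrid()


@pytest.fixture(scope="session")
def references(grid):
    return pp.build_reference_spectra(grid)


@pytest.fixture(scope="session")
def default_rates():
    return pp.KineticRates()


@pytest.fixture(scope="session")
def cell_centered_stack(default_rates):
    """Noiseless conversion series of a single soma under a tight ROI,
    for parameter-recovery checks."""
    scene = sd.generate_scene(field_um=60.0, n_cells=1, seed=3,
                              min_dist_um=10.0)
    scene.cells[0].soma_xy_um = (30.0, 30.0)
    return sd.simulate_conversion_series(
        scene, (18.0, 18.0, 42.0, 42.0), pp.IN_VIVO_LOCAL, default_rates,
        noise=sd.NOISELESS, n_scans=40, px_size_um=3.0)


@pytest.fixture(scope="session")
def injury_setup():
    field = 1456.0
    inj_center = (field / 2.0, field / 2.0)
    conv_roi = (field / 2.0 + 365.0 - 182.5, field / 2.0 - 182.5,
                field / 2.0 + 365.0 + 182.5, field / 2.0 + 182.5)
    scene = sd.generate_scene(field_um=field, n_cells=80, seed=7,
                              min_dist_um=80.0,
                              injury=(inj_center, 150.0))
    return scene, conv_roi, inj_center


@pytest.fixture(scope="session")
def injury_frames(injury_setup, default_rates):
    scene, conv_roi, _ = injury_setup
    frames, evolved = sd.simulate_longitudinal(
        scene, conv_roi, pp.IN_VIVO_LOCAL, default_rates, days=7,
        scenario="injury", noise=sd.NoiseModel())
    return frames, evolved


@pytest.fixture(scope="session")
def injury_series(injury_frames, injury_setup):
    frames, _ = injury_frames
    _, _, inj_center = injury_setup
    roi = ia.RegionOfInterest(center_um=inj_center)
    return ia.injury_response_series(frames, roi)


@pytest.fixture(scope="session")
def converted_flow():
    return sd.generate_flow_sample(sd.CONVERTED_SPEC, seed=11)


@pytest.fixture(scope="session")
def unconverted_flow():
    return sd.generate_flow_sample(sd.UNCONVERTED_SPEC, seed=12)
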