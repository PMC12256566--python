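import numpy as np
import pytest

from sbrtaudit.cases import get_case
from sbrtaudit.film import fit_calibration
from sbrtaudit.synthetic import (
    FilmForwardModel,
    make_calibration_dataset,
    make_phantom_plane,
    make_planned_dose,
)

_CACHE = {}


def case_setup(case_id, grid_shape=(200, 200), spacing=0.5):
    """Cached (phantom, case, planned) triple for one audit case."""
    key = (case_id, grid_shape, spacing)
    if key not in _CACHE:
        phantom = make_phantom_plane(case_id, grid_shape, spacing)
        case = get_case(case_id)
        _CACHE[key] = (phantom, case, make_planned_dose(phantom, case))
    return _CACHE[key]


@pytest.fixture(scope="session")
def film_model():
    return FilmForwardModel()


@pytest.fixture(scope="session")
def noiseless_film_model():
    return FilmForwardModel(noise_sigma=0.0)


@pytest.fixture(scope="session")
def calibration_model(noiseless_film_model):
    return fit_calibration(
        make_calibration_dataset(noiseless_film_model),
        darkening=noiseless_film_model.darkening,
    )
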