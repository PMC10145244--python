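import numpy as np
import pytest

from geopest.samples import InstarGroup, SamplePoint, SurveyDesign
from geopest.synthetic import SimulationConfig, simulate_survey
from geopest.variogram import VariogramModel


@pytest.fixture(scope="session")
def survey_points():
    """One default synthetic survey (63 plants), fixed seed."""
    return simulate_survey(SimulationConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def spherical_model():
    return VariogramModel("spherical", nugget=0.100, sill=0.260, range=52.5)


def make_points(coords, values, group=InstarGroup.I3):
    """Minimal sample points from coordinate/value arrays."""
    return [
        SamplePoint(id=f"s{i}", x=float(x), y=float(y), counts={group: int(v)})
        for i, ((x, y), v) in enumerate(zip(coords, values))
    ]


def random_points(rng, n, extent=100.0, max_count=20, group=InstarGroup.I3):
    coords = rng.uniform(0, extent, size=(n, 2))
    values = rng.integers(0, max_count, size=n)
    return make_points(coords, values, group), coords, values.astype(float)
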