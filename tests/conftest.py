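import pytest

from lakeburial.geochron import CoreInterval, CoreProfile, crs_date
from lakeburial.synth import CoreScenario, make_core


@pytest.fixture(scope="session")
def ideal_core():
    """Noiseless constant-flux, constant-rate core with its truth record."""
    return make_core(CoreScenario())


@pytest.fixture(scope="session")
def ideal_dated(ideal_core):
    profile, truth = ideal_core
    return crs_date(profile), truth


def make_simple_profile(totals, ra=20.0, rho=1.0, thickness=2.0, oc=5.0):
    """A minimal hand-built profile from a list of total ²¹⁰Pb activities."""
    intervals = [
        CoreInterval(
            top_depth=i * thickness,
            thickness=thickness,
            dry_bulk_density=rho,
            pb210_total=float(t),
            ra226=ra,
            oc_percent=oc,
        )
        for i, t in enumerate(totals)
    ]
    return CoreProfile("test", intervals, collection_year=2015)


@pytest.fixture
def simple_profile():
    return make_simple_profile([50.0, 40.0, 32.0, 26.0, 22.0])
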