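import numpy as np
import pytest

from mradcast.records import Dataset, DeathRecord, ObservationWindow
from mradcast.simulate import fixture_small


def make_dataset(excess_ages, window=None, country="US", attainment_time=2000.0):
    """Dataset with the given excess ages, one country, shared attainment
    time; default window is unbounded starting well before attainment, so
    the data are effectively untruncated."""
    if window is None:
        window = ObservationWindow(country=country, start=1900.0)
    records = [
        DeathRecord(
            record_id=f"r{i}",
            country=country,
            sex="F",
            attainment_time=attainment_time,
            death_time=attainment_time + float(x),
            excess_age=float(x),
        )
        for i, x in enumerate(excess_ages)
    ]
    return Dataset(records, {country: window})


def untruncated_exponential_dataset(n, rate, seed):
    rng = np.random.default_rng(seed)
    return make_dataset(rng.exponential(scale=1.0 / rate, size=n))


@pytest.fixture(scope="session")
def small_fixture():
    return fixture_small()


@pytest.fixture
def fixture_dataset(small_fixture):
    return small_fixture[0]


@pytest.fixture
def fixture_trajectories(small_fixture):
    return small_fixture[1]
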