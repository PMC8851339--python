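import pytest

import handrisk as hr


@pytest.fixture(scope="session")
def fixture_zones():
    return hr.fixture_zone_table()


@pytest.fixture(scope="session")
def fixture_events():
    return hr.fixture_worked_example()


@pytest.fixture(scope="session")
def fixture_metrics(fixture_events, fixture_zones):
    visits = hr.sessionize(fixture_events, fixture_zones)
    return hr.compute_metrics(visits, fixture_zones)


def small_scenario(seed: int, **overrides) -> "hr.SimScenario":
    """A few staff over a couple of days; quick to replay."""
    base = dict(
        n_staff=3,
        room_ids=["1101", "1102", "1103", "1104"],
        n_days=2,
        compliance_prob=0.6,
        visits_per_staff_day=6.0,
        seed=seed,
    )
    base.update(overrides)
    return hr.SimScenario(**base)


@pytest.fixture
def small_sim():
    return hr.simulate(small_scenario(seed=42))
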