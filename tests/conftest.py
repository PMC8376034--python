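import datetime as dt

import pytest

from smsri.codec import default_code_table
from smsri.ingest import run_pipeline
from smsri.quality import Window
from smsri.registry import HealthFacility, Registry
from smsri.simulate import pilot_fixture


@pytest.fixture(scope="session")
def table():
    return default_code_table()


@pytest.fixture
def small_registry():
    """Three-type fleet: 3 hospitals, 6 urban PHCs, 41 primary HFs."""
    facilities = []
    idx = 0
    for ftype, n, fixed in (("hospital", 3, 5), ("urban_phc", 6, 2),
                            ("primary_hf", 41, 1)):
        for _ in range(n):
            idx += 1
            facilities.append(HealthFacility(
                facility_id=f"F{idx:02d}",
                name=f"{ftype} {idx}",
                district="Keffi" if idx % 2 else "Keana",
                facility_type=ftype,
                phone=f"0805{idx:07d}",
                planned_fixed_per_week=fixed,
                planned_outreach_per_week=1,
                active=True,
            ))
    return Registry(facilities)


@pytest.fixture
def one_week():
    # Monday 2018-01-08 .. Sunday 2018-01-14
    return Window(dt.date(2018, 1, 8), dt.date(2018, 1, 14))


@pytest.fixture(scope="session")
def pilot():
    """The packaged pilot fixture, interpreted once per test session."""
    fx = pilot_fixture()
    result = run_pipeline(fx.messages, fx.registry, fx.code_table)
    return fx, result
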