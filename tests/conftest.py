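import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from heatsense.pipeline import RunConfig, run_pipeline
from heatsense.qc_labeling import build_heatwave_calendar
from heatsense.synthetic_cohort import ScenarioConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_REGION_SPECS = [
    ("Montréal", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Laval", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Montérégie", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
    ("Outaouais", dt.date(2018, 6, 30), dt.date(2018, 7, 5)),
]


@pytest.fixture(scope="session")
def small_calendar():
    """Default heat-wave ranges trimmed to the short test window."""
    return build_heatwave_calendar(SMALL_REGION_SPECS)


@pytest.fixture(scope="session")
def small_scenario(small_calendar):
    """12 AC + 12 non-AC houses over 16 days spanning the heat wave."""
    return ScenarioConfig(
        n_ac_houses=12,
        n_nonac_houses=12,
        date_start=dt.date(2018, 6, 25),
        date_end=dt.date(2018, 7, 10),
        heatwave_calendar=small_calendar,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_scenario, small_calendar, tmp_path_factory):
    """One completed pipeline run on the small cohort (manifest, out_dir)."""
    out_dir = tmp_path_factory.mktemp("small_run")
    config = RunConfig(
        out_dir=out_dir,
        scenario=small_scenario,
        calendar=small_calendar,
        min_houses=2,
    )
    manifest = run_pipeline(config)
    return manifest, out_dir
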