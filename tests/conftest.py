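import pandas as pd
import pytest

from overuse_pipeline import (
    SyntheticCohortConfig,
    aggregate_days,
    classify_days,
    generate_cohort,
    load_events,
)

START = pd.Timestamp("2020-03-01")


def day(n: int) -> pd.Timestamp:
    """Calendar day n of the canonical test monitoring period."""
    return START + pd.Timedelta(days=n)


def make_participants(ids, arm="SMART", n_days=168):
    return pd.DataFrame(
        {
            "participant_id": list(ids),
            "arm": arm if isinstance(arm, str) else list(arm),
            "monitor_start": START,
            "monitor_end": START + pd.Timedelta(days=n_days - 1),
        }
    )


def make_days(pid, counts_by_day, arm="SMART", med="bud", n_days=168):
    """Day-record frame for one participant from {day_number: count}."""
    col = "bud_form_actuations" if med == "bud" else "salbutamol_actuations"
    other = "salbutamol_actuations" if med == "bud" else "bud_form_actuations"
    rows = [
        {"participant_id": pid, "date": day(n), col: counts_by_day.get(n, 0), other: 0}
        for n in range(n_days)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticCohortConfig(n_smart=25, n_standard=25, n_days=84)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    return load_events(
        small_tables["actuations"], small_tables["reviews"],
        small_tables["ocs"], small_tables["participants"],
    )


@pytest.fixture(scope="session")
def small_classified(small_cohort):
    days = aggregate_days(small_cohort)
    return classify_days(days, small_cohort.participants)


@pytest.fixture(scope="session")
def default_tables():
    """A full-size synthetic cohort at the default study conditions."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_tables):
    return load_events(
        default_tables["actuations"], default_tables["reviews"],
        default_tables["ocs"], default_tables["participants"],
    )


@pytest.fixture(scope="session")
def default_classified(default_cohort):
    days = aggregate_days(default_cohort)
    return classify_days(days, default_cohort.participants)
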