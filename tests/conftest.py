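"""Shared fixtures: the default synthetic cohort and its clustering.

Session-scoped because the cohort generation (~0.5 s) and the k=4
clustering (~5 s) feed many tests; everything downstream treats them as
read-only.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from bpengage import (
    default_cohort_spec,
    generate_cohort,
    apply_inclusion_filters,
    extract_trajectories,
    kmeans_dtw,
)
from bpengage.eventlog import EventLog

COHORT_SEED = 1
CLUSTER_SEED = 7
ANALYSIS_WEEKS = [1, 2, 3, 4]


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_log(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def included_and_report(default_log):
    return apply_inclusion_filters(default_log)


@pytest.fixture(scope="session")
def included(included_and_report):
    return included_and_report[0]


@pytest.fixture(scope="session")
def trajectories(included):
    return extract_trajectories(included)


@pytest.fixture(scope="session")
def pe(trajectories):
    return trajectories[0]


@pytest.fixture(scope="session")
def sbp(trajectories):
    return trajectories[1]


@pytest.fixture(scope="session")
def truth_labels(default_log, pe) -> pd.Series:
    return default_log.truth.set_index("patient_id")["archetype"].loc[pe.index]


@pytest.fixture(scope="session")
def clustering(pe):
    return kmeans_dtw(pe[ANALYSIS_WEEKS], k=4, seed=CLUSTER_SEED, n_init=10)


def make_log(patients, bp=(), followups=(), truth=None) -> EventLog:
    """Build a small EventLog from plain tuples (test helper).

    ``patients``: (pid, birth, gender, education, registration);
    ``bp``: (pid, timestamp, sbp, dbp); ``followups``: (pid, date, type).
    """
    demo = pd.DataFrame(
        patients, columns=["patient_id", "birth_date", "gender", "education", "registration_date"]
    )
    bp_records = pd.DataFrame(
        list(bp), columns=["patient_id", "timestamp", "sbp_mmhg", "dbp_mmhg"]
    )
    fu = pd.DataFrame(list(followups), columns=["patient_id", "date", "type"])
    truth_df = None
    if truth is not None:
        truth_df = pd.DataFrame(list(truth), columns=["patient_id", "archetype"])
    return EventLog(demo, bp_records, fu, truth=truth_df)


def day(reg: dt.date, offset: int, hour: int = 9) -> dt.datetime:
    return dt.datetime.combine(reg + dt.timedelta(days=offset), dt.time(hour, 0, 0))
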