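"""Inclusion filtering and weekly trajectory extraction.

Engagement is the number of distinct calendar dates per week on which a
patient recorded a blood-pressure value (an integer 0..7); the weekly SBP
series is the mean of all systolic values recorded in that week.  Weeks
are anchored at the registration date: week *w* spans days
``[7(w-1), 7w)`` after registration, with day boundaries at midnight of
the date field.  Diastolic pressure is read but never analyzed.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .cohort import STUDY_WINDOW_START, STUDY_WINDOW_END, DEFAULT_HORIZON_WEEKS
from .eventlog import EventLog

#: Exclusion rules in attribution order (first matching rule wins).
EXCLUSION_RULES = ("age", "window", "duration")

MIN_AGE_YEARS = 18
MIN_RECORD_SPAN_DAYS = 28  # span must be strictly greater


def age_at(birth: dt.date, on: dt.date) -> int:
    """Age in whole years on a given date."""
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def apply_inclusion_filters(
    log: EventLog,
    window_start: dt.date = STUDY_WINDOW_START,
    window_end: dt.date = STUDY_WINDOW_END,
    strict_weekly: bool = False,
) -> tuple[EventLog, pd.DataFrame]:
    """Apply the study inclusion criteria; returns (filtered log, exclusions).

    A patient is retained when, in this order of attribution:

    1. ``age``      — at least 18 years old at registration;
    2. ``window``   — registered within ``[window_start, window_end]``;
    3. ``duration`` — recorded BP for more than 4 weeks, operationalized as
       (last record date - first record date) > 28 days.  With
       ``strict_weekly=True`` the stricter reading "at least one record in
       each of the first 4 weeks" is required as well.

    The exclusion report has one row per excluded patient with the first
    rule that patient violates.  Filtering is idempotent.
    """
    demo = log.demographics
    first_last = (
        log.bp_records.assign(date=lambda f: f["timestamp"].map(lambda t: t.date()))
        .groupby("patient_id")["date"]
        .agg(["min", "max"])
    )

    kept, excluded = [], []
    for _, row in demo.iterrows():
        pid = row["patient_id"]
        reg = row["registration_date"]
        if age_at(row["birth_date"], reg) < MIN_AGE_YEARS:
            excluded.append((pid, "age"))
            continue
        if not (window_start <= reg <= window_end):
            excluded.append((pid, "window"))
            continue
        if pid not in first_last.index:
            excluded.append((pid, "duration"))
            continue
        span = (first_last.at[pid, "max"] - first_last.at[pid, "min"]).days
        if span <= MIN_RECORD_SPAN_DAYS:
            excluded.append((pid, "duration"))
            continue
        if strict_weekly:
            days = {
                (d - reg).days // 7
                for d in log.bp_records.loc[log.bp_records["patient_id"] == pid, "timestamp"].map(
                    lambda t: t.date()
                )
                if 0 <= (d - reg).days < 28
            }
            if days != {0, 1, 2, 3}:
                excluded.append((pid, "duration"))
                continue
        kept.append(pid)

    report = pd.DataFrame(excluded, columns=["patient_id", "rule"])
    return log.subset(kept), report


def extract_trajectories(
    log: EventLog, weeks: int = DEFAULT_HORIZON_WEEKS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient weekly engagement and weekly mean SBP.

    Returns ``(pe, sbp)``: DataFrames indexed by ``patient_id`` with one
    integer (resp. float, NaN-able) column per week ``1..weeks``.  ``pe``
    counts distinct record dates per week (intra-day duplicates count
    once); ``sbp`` averages every systolic value in the week and is missing
    exactly when the week has no records.
    """
    demo = log.demographics.set_index("patient_id")
    ids = demo.index
    week_cols = list(range(1, weeks + 1))
    pe = pd.DataFrame(0, index=ids, columns=week_cols, dtype=int)
    sbp = pd.DataFrame(np.nan, index=ids, columns=week_cols, dtype=float)

    if len(log.bp_records):
        rec = log.bp_records[["patient_id", "timestamp", "sbp_mmhg"]].copy()
        rec["date"] = rec["timestamp"].map(lambda t: t.date())
        rec["offset"] = [
            (d - demo.at[pid, "registration_date"]).days
            for pid, d in zip(rec["patient_id"], rec["date"])
        ]
        rec = rec[(rec["offset"] >= 0) & (rec["offset"] < 7 * weeks)]
        rec["week"] = rec["offset"] // 7 + 1

        counts = rec.groupby(["patient_id", "week"])["date"].nunique()
        means = rec.groupby(["patient_id", "week"])["sbp_mmhg"].mean()
        pe_w = counts.unstack("week")
        sbp_w = means.unstack("week")
        pe.loc[pe_w.index, pe_w.columns] = pe_w.fillna(0).astype(int)
        sbp.loc[sbp_w.index, sbp_w.columns] = sbp_w

    pe.index.name = sbp.index.name = "patient_id"
    return pe, sbp


def write_trajectories(pe: pd.DataFrame, sbp: pd.DataFrame, path) -> None:
    """trajectories.csv: patient_id, pe_w1.., sbp_w1.. (empty = missing)."""
    out = pd.concat(
        [pe.rename(columns=lambda w: f"pe_w{w}"), sbp.rename(columns=lambda w: f"sbp_w{w}")],
        axis=1,
    )
    out.to_csv(path, index=True)
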