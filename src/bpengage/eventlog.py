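"""Event-log container and delimited-text round trip.

An :class:`EventLog` bundles the three record tables an mHealth
blood-pressure service accumulates per patient:

* ``demographics`` — one row per registered patient,
* ``bp_records``   — one row per uploaded blood-pressure measurement,
* ``followups``    — one row per provider follow-up contact.

Synthetic logs additionally carry a ``truth`` table with the planted
engagement archetype of each patient; real logs have no such table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FOLLOWUP_TYPES = ("compliance", "regular", "abnormal")
GENDERS = ("male", "female")
EDUCATION_LEVELS = ("primary_secondary", "high_school", "university_plus")

SBP_MIN, SBP_MAX = 50.0, 300.0  # physiologic plausibility bounds, mmHg

_DEMO_COLS = ["patient_id", "birth_date", "gender", "education", "registration_date"]
_BP_COLS = ["patient_id", "timestamp", "sbp_mmhg", "dbp_mmhg"]
_FU_COLS = ["patient_id", "date", "type"]
_TRUTH_COLS = ["patient_id", "archetype"]


class EventLogError(ValueError):
    """Raised when an event log fails structural validation.

    ``errors`` lists human-readable messages; file-backed logs include the
    offending file and 1-based line number.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "\n".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n... and {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} event-log validation error(s):\n{preview}{more}")


@dataclass
class EventLog:
    demographics: pd.DataFrame
    bp_records: pd.DataFrame
    followups: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.demographics = self.demographics.reindex(columns=_DEMO_COLS)
        self.bp_records = self.bp_records.reindex(columns=_BP_COLS)
        self.followups = self.followups.reindex(columns=_FU_COLS)
        if self.truth is not None:
            self.truth = self.truth.reindex(columns=_TRUTH_COLS)
        self._sort()

    def _sort(self) -> None:
        self.demographics = self.demographics.sort_values("patient_id", kind="stable").reset_index(drop=True)
        self.bp_records = self.bp_records.sort_values(
            ["patient_id", "timestamp"], kind="stable"
        ).reset_index(drop=True)
        self.followups = self.followups.sort_values(
            ["patient_id", "date", "type"], kind="stable"
        ).reset_index(drop=True)
        if self.truth is not None:
            self.truth = self.truth.sort_values("patient_id", kind="stable").reset_index(drop=True)

    # -- structural checks -------------------------------------------------

    def validate(self) -> "EventLog":
        errors: list[str] = []
        ids = self.demographics["patient_id"]
        if ids.duplicated().any():
            for pid in ids[ids.duplicated()].unique():
                errors.append(f"demographics: duplicate patient_id {pid!r}")
        known = set(ids)
        for tab, frame, datecol in (
            ("bp_records", self.bp_records, "timestamp"),
            ("followups", self.followups, "date"),
        ):
            orphan = ~frame["patient_id"].isin(known)
            for row in frame.index[orphan]:
                errors.append(f"{tab} row {row}: unknown patient_id {frame.at[row, 'patient_id']!r}")
        bad_sbp = ~self.bp_records["sbp_mmhg"].between(SBP_MIN, SBP_MAX, inclusive="neither")
        for row in self.bp_records.index[bad_sbp]:
            errors.append(
                f"bp_records row {row}: sbp_mmhg {self.bp_records.at[row, 'sbp_mmhg']} "
                f"outside ({SBP_MIN:g}, {SBP_MAX:g})"
            )
        bad_type = ~self.followups["type"].isin(FOLLOWUP_TYPES)
        for row in self.followups.index[bad_type]:
            errors.append(f"followups row {row}: unknown type {self.followups.at[row, 'type']!r}")
        if errors:
            raise EventLogError(errors)
        return self

    def subset(self, patient_ids) -> "EventLog":
        """Restrict every table to the given patients (order preserved)."""
        keep = set(patient_ids)
        return EventLog(
            demographics=self.demographics[self.demographics["patient_id"].isin(keep)].copy(),
            bp_records=self.bp_records[self.bp_records["patient_id"].isin(keep)].copy(),
            followups=self.followups[self.followups["patient_id"].isin(keep)].copy(),
            truth=None if self.truth is None else self.truth[self.truth["patient_id"].isin(keep)].copy(),
        )

    def equals(self, other: "EventLog") -> bool:
        if not (
            self.demographics.equals(other.demographics)
            and self.bp_records.equals(other.bp_records)
            and self.followups.equals(other.followups)
        ):
            return False
        if (self.truth is None) != (other.truth is None):
            return False
        return self.truth is None or self.truth.equals(other.truth)

    # -- persistence -------------------------------------------------------

    def write(self, directory: str | Path) -> list[Path]:
        """Write the delimited tables; returns the written paths.

        Dates are ISO-8601; timestamps ISO-8601 to the second.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        frames = {
            "demographics.csv": _stringify_dates(self.demographics, ["birth_date", "registration_date"]),
            "bp_records.csv": _stringify_dates(self.bp_records, [], ts_cols=["timestamp"]),
            "followups.csv": _stringify_dates(self.followups, ["date"]),
        }
        if self.truth is not None:
            frames["truth.csv"] = self.truth
        for name, frame in frames.items():
            path = directory / name
            frame.to_csv(path, index=False)
            paths.append(path)
        return paths


def _stringify_dates(frame: pd.DataFrame, date_cols: list[str], ts_cols: list[str] | None = None) -> pd.DataFrame:
    out = frame.copy()
    for col in date_cols:
        out[col] = out[col].map(lambda d: d.isoformat())
    for col in ts_cols or []:
        out[col] = out[col].map(lambda t: t.strftime("%Y-%m-%dT%H:%M:%S"))
    return out


def write_cohort(log: EventLog, directory: str | Path) -> list[Path]:
    """Alias for :meth:`EventLog.write` (generator-facing name)."""
    return log.write(directory)


def _parse(frame: pd.DataFrame, col: str, parser, kind: str, fname: str, errors: list[str]):
    parsed = []
    for row, raw in frame[col].items():
        try:
            parsed.append(parser(raw))
        except (ValueError, TypeError):
            # +2: header line plus 1-based numbering
            errors.append(f"{fname} line {row + 2}: cannot parse {kind} {raw!r} in column {col!r}")
            parsed.append(None)
    frame[col] = parsed


def read_event_log(directory: str | Path) -> EventLog:
    """Parse and validate the three delimited tables under ``directory``.

    Raises :class:`EventLogError` naming file and line for malformed rows,
    out-of-range systolic pressures and orphan patient ids; raises
    ``FileNotFoundError`` for a missing table.
    """
    directory = Path(directory)
    errors: list[str] = []
    for name in ("demographics.csv", "bp_records.csv", "followups.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(directory / name)

    demo = pd.read_csv(directory / "demographics.csv", dtype=str)
    bp = pd.read_csv(directory / "bp_records.csv", dtype=str)
    fu = pd.read_csv(directory / "followups.csv", dtype=str)
    for frame, cols, name in ((demo, _DEMO_COLS, "demographics.csv"),
                              (bp, _BP_COLS, "bp_records.csv"),
                              (fu, _FU_COLS, "followups.csv")):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            errors.append(f"{name}: missing column(s) {missing}")
    if errors:
        raise EventLogError(errors)

    _parse(demo, "birth_date", dt.date.fromisoformat, "date", "demographics.csv", errors)
    _parse(demo, "registration_date", dt.date.fromisoformat, "date", "demographics.csv", errors)
    _parse(bp, "timestamp", dt.datetime.fromisoformat, "timestamp", "bp_records.csv", errors)
    _parse(bp, "sbp_mmhg", float, "number", "bp_records.csv", errors)
    _parse(bp, "dbp_mmhg", float, "number", "bp_records.csv", errors)
    _parse(fu, "date", dt.date.fromisoformat, "date", "followups.csv", errors)
    if errors:
        raise EventLogError(errors)

    truth = None
    if (directory / "truth.csv").exists():
        truth = pd.read_csv(directory / "truth.csv", dtype=str)

    log = EventLog(demographics=demo, bp_records=bp, followups=fu, truth=truth)
    return log.validate()
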