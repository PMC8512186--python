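"""Synthetic cohort generator for a hypertension self-monitoring service.

The generator emits per-patient event logs (demographics, BP records,
provider follow-ups) whose statistical structure matches the published
summary tables of a four-archetype engagement cohort:

* four latent engagement archetypes (PELL, PEHH, PEHL, PELH) with weekly
  engagement means/SDs and sizes 183/142/148/89;
* exact demographic margins (age band x gender x education) per archetype;
* exact first-week systolic-BP stratum counts per archetype;
* exact follow-up counts per (archetype, type) and (archetype, week);
* injectable per-follow-up effects on next-week engagement and SBP, so the
  downstream pre-post estimator has a known ground truth to recover.

Weekly engagement is drawn as ``round(clip(Normal(mu_w, sd_w), 0, 7))``.
Because the study's inclusion rule (recording span > 28 days inside a
35-day horizon) implies every *selected* patient recorded early and late,
planted passers record on day 0 and at least once on days 29-34; their
week-1 and internal week-5 counts are therefore clamped to >= 1.  The
published weekly means describe the post-selection cohort, so this is part
of emulating selection, not a bias knob.

After a follow-up event in week *w*, the patient's pre-noise engagement
level for week *w+1* is the realized week-*w* count plus the injected
engagement effect, and the SBP level for week *w+1* is the week-*w* level
plus the injected SBP effect (replacing the archetype drift for that
transition).  The injected value is thus exactly the estimand of the
week-over-week change estimator.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .eventlog import EventLog, write_cohort  # noqa: F401  (re-exported)

ARCHETYPES = ("PELL", "PEHH", "PEHL", "PELH")
AGE_BANDS = ("18-40", "40-60", ">60")

STUDY_WINDOW_START = dt.date(2016, 3, 27)
STUDY_WINDOW_END = dt.date(2019, 7, 10)

#: Internal simulation horizon (weeks). One week beyond the 4 analyzed weeks
#: so that week-4 follow-ups have a "week after".
DEFAULT_HORIZON_WEEKS = 5

# ---------------------------------------------------------------------------
# Published cohort structure (defaults)
# ---------------------------------------------------------------------------

ARCHETYPE_SIZES = {"PELL": 183, "PEHH": 142, "PEHL": 148, "PELH": 89}

WEEKLY_PE_MEAN = {
    "PELL": (1.9, 0.8, 0.8, 0.6),
    "PEHH": (6.4, 6.6, 6.4, 6.3),
    "PEHL": (5.8, 4.8, 3.2, 1.8),
    "PELH": (2.4, 3.5, 4.3, 4.6),
}
WEEKLY_PE_SD = {
    "PELL": (1.1, 1.3, 1.3, 0.8),
    "PEHH": (1.1, 0.8, 0.9, 0.9),
    "PEHL": (1.2, 1.9, 2.1, 1.3),
    "PELH": (1.3, 2.0, 2.0, 1.5),
}

#: Demographic margins per archetype: counts by age band, gender, education.
DEMOGRAPHIC_MARGINS = {
    "PELL": {
        "age": {"18-40": 24, "40-60": 131, ">60": 28},
        "gender": {"male": 102, "female": 81},
        "education": {"primary_secondary": 14, "high_school": 79, "university_plus": 90},
    },
    "PEHH": {
        "age": {"18-40": 14, "40-60": 86, ">60": 42},
        "gender": {"male": 84, "female": 58},
        "education": {"primary_secondary": 6, "high_school": 61, "university_plus": 75},
    },
    "PEHL": {
        "age": {"18-40": 27, "40-60": 104, ">60": 17},
        "gender": {"male": 95, "female": 53},
        "education": {"primary_secondary": 5, "high_school": 68, "university_plus": 75},
    },
    "PELH": {
        "age": {"18-40": 11, "40-60": 66, ">60": 12},
        "gender": {"male": 57, "female": 32},
        "education": {"primary_secondary": 2, "high_school": 43, "university_plus": 44},
    },
}

#: First-week mean-SBP stratum counts per archetype, bands
#: <120, 120-139, 140-159, 160-179, >=180 mmHg.
SBP_STRATUM_COUNTS = {
    "PELL": (19, 90, 53, 16, 5),
    "PEHH": (13, 91, 35, 3, 0),
    "PEHL": (23, 91, 32, 2, 0),
    "PELH": (7, 44, 34, 4, 0),
}
SBP_STRATUM_BANDS = ((100.0, 119.0), (120.0, 139.0), (140.0, 159.0), (160.0, 179.0), (180.0, 195.0))

#: Follow-up counts per archetype by type and by calendar week of the event.
#: The two tabulations are taken as independent marginal constraints (their
#: grand totals differ: 661 by type vs 680 by week); the generator realizes
#: the week margin exactly and rescales the type margin to the same total by
#: largest-remainder rounding.
FOLLOWUP_TYPE_COUNTS = {
    "PELL": {"compliance": 77, "regular": 80, "abnormal": 10},
    "PEHH": {"compliance": 53, "regular": 87, "abnormal": 29},
    "PEHL": {"compliance": 74, "regular": 85, "abnormal": 30},
    "PELH": {"compliance": 57, "regular": 61, "abnormal": 18},
}
FOLLOWUP_WEEK_COUNTS = {
    "PELL": {1: 90, 2: 50, 3: 13, 4: 21},
    "PEHH": {1: 86, 2: 44, 3: 14, 4: 27},
    "PEHL": {1: 96, 2: 40, 3: 23, 4: 36},
    "PELH": {1: 66, 2: 36, 3: 23, 4: 15},
}

#: Published mean change in engagement (days/week) after a follow-up, by
#: follow-up type — the default engagement injection.
INJECTED_CPE_BY_TYPE = {
    "PELL": {"compliance": -0.6, "regular": -0.1, "abnormal": -0.1},
    "PEHH": {"compliance": 0.5, "regular": -0.2, "abnormal": -0.1},
    "PEHL": {"compliance": -0.3, "regular": -1.1, "abnormal": -1.8},
    "PELH": {"compliance": 1.31, "regular": 0.67, "abnormal": -0.39},
}
#: Published mean change in weekly-mean SBP (mmHg) after a follow-up, by
#: week of the event — the default SBP injection.
INJECTED_CSBP_BY_WEEK = {
    "PELL": {1: -6.1, 2: -2.1, 3: 1.4, 4: 2.6},
    "PEHH": {1: -3.0, 2: -1.3, 3: -3.2, 4: -1.7},
    "PEHL": {1: -2.5, 2: -0.1, 3: 2.2, 4: -3.7},
    "PELH": {1: -8.4, 2: -4.2, 3: -0.3, 4: -3.4},
}

#: Weekly SBP drift (mmHg per week-to-week transition) in the absence of a
#: follow-up, chosen to mimic the reported qualitative trend: every archetype
#: declines early; the lowest-engagement group rebounds in week 4.
WEEKLY_SBP_DRIFT = {
    "PELL": (-4.0, -5.0, 3.0, 0.0),
    "PEHH": (-2.0, -2.0, -2.0, -1.0),
    "PEHL": (-1.0, -2.0, 1.0, -1.0),
    "PELH": (-5.0, -3.0, -1.0, -1.0),
}

#: Within-week SBP measurement noise around the weekly level, mmHg.
SBP_RECORD_NOISE_SD = 5.0


def largest_remainder(proportions, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder method."""
    proportions = np.asarray(proportions, dtype=float)
    if proportions.sum() <= 0:
        raise ValueError("proportions must have positive sum")
    quota = proportions / proportions.sum() * total
    base = np.floor(quota + 1e-9).astype(int)
    short = total - base.sum()
    if short:
        frac = quota - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeSpec:
    """Latent engagement archetype: weekly engagement law and SBP structure."""

    name: str
    weekly_pe_mean: tuple[float, ...]  # days/week, analysis weeks 1..4
    weekly_pe_sd: tuple[float, ...]
    size: int
    sbp_week1_strata: tuple[float, ...]  # probabilities over the 5 SBP bands
    weekly_sbp_drift: tuple[float, ...]  # mmHg, transitions w -> w+1

    def __post_init__(self) -> None:
        if not all(0.0 <= m <= 7.0 for m in self.weekly_pe_mean):
            raise ValueError(f"{self.name}: weekly_pe_mean entries must lie in [0, 7]")
        if self.size < 0:
            raise ValueError(f"{self.name}: size must be >= 0")
        if abs(sum(self.sbp_week1_strata) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: sbp_week1_strata must sum to 1")
        if len(self.weekly_pe_mean) != len(self.weekly_pe_sd):
            raise ValueError(f"{self.name}: mean/sd length mismatch")

    def mean_at(self, week: int) -> float:
        """Archetype mean for 1-based ``week``; constant beyond the last stated week."""
        return self.weekly_pe_mean[min(week, len(self.weekly_pe_mean)) - 1]

    def sd_at(self, week: int) -> float:
        return self.weekly_pe_sd[min(week, len(self.weekly_pe_sd)) - 1]

    def drift_at(self, week: int) -> float:
        """SBP drift applied on the transition out of 1-based ``week``."""
        return self.weekly_sbp_drift[min(week, len(self.weekly_sbp_drift)) - 1]


@dataclass(frozen=True)
class FollowUpPlan:
    """Follow-up counts (two marginal views) and injectable effects.

    ``injected_cpe`` / ``injected_csbp`` map ``(archetype, key)`` to an
    effect, where ``key`` is a follow-up type string or an integer event
    week; an event accumulates every entry matching its archetype and its
    own type/week.
    """

    type_counts_by_cluster: dict[str, dict[str, int]]
    week_counts_by_cluster: dict[str, dict[int, int]]
    injected_cpe: dict[tuple[str, object], float] = field(default_factory=dict)
    injected_csbp: dict[tuple[str, object], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for margin in (self.type_counts_by_cluster, self.week_counts_by_cluster):
            for cluster, counts in margin.items():
                for key, n in counts.items():
                    if n < 0:
                        raise ValueError(f"negative follow-up count for ({cluster}, {key})")
        for effects in (self.injected_cpe, self.injected_csbp):
            for key, v in effects.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite injected effect for {key}")

    def total_events(self, cluster: str) -> int:
        return sum(self.week_counts_by_cluster.get(cluster, {}).values())

    def effective_type_counts(self, cluster: str) -> dict[str, int]:
        """Type margin rescaled to the week-margin total by largest remainder."""
        raw = self.type_counts_by_cluster.get(cluster, {})
        types = list(raw)
        if not types or sum(raw.values()) == 0 or self.total_events(cluster) == 0:
            return {t: 0 for t in types}
        counts = largest_remainder([raw[t] for t in types], self.total_events(cluster))
        return dict(zip(types, (int(c) for c in counts)))

    def shift_for(self, effects: dict, cluster: str, ftype: str, week: int) -> float:
        return effects.get((cluster, ftype), 0.0) + effects.get((cluster, week), 0.0)


@dataclass(frozen=True)
class CohortSpec:
    archetypes: tuple[ArchetypeSpec, ...]
    followup_plan: FollowUpPlan
    demographics_margins: dict[str, dict[str, dict[str, int]]]
    n_excluded_patients: int = 50
    seed: int = 0
    horizon_weeks: int = DEFAULT_HORIZON_WEEKS
    window_start: dt.date = STUDY_WINDOW_START
    window_end: dt.date = STUDY_WINDOW_END

    def __post_init__(self) -> None:
        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise ValueError("archetype names must be unique")
        if self.horizon_weeks < 2:
            raise ValueError("horizon must cover at least 2 weeks")

    @property
    def total_passing(self) -> int:
        return sum(a.size for a in self.archetypes)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=int(seed))

    # -- plain-text config round trip --------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "horizon_weeks": self.horizon_weeks,
            "n_excluded_patients": self.n_excluded_patients,
            "window_start": self.window_start.isoformat(),
            "window_end": self.window_end.isoformat(),
            "archetypes": [
                {
                    "name": a.name,
                    "weekly_pe_mean": list(a.weekly_pe_mean),
                    "weekly_pe_sd": list(a.weekly_pe_sd),
                    "size": a.size,
                    "sbp_week1_strata": list(a.sbp_week1_strata),
                    "weekly_sbp_drift": list(a.weekly_sbp_drift),
                }
                for a in self.archetypes
            ],
            "followup_plan": {
                "type_counts_by_cluster": self.followup_plan.type_counts_by_cluster,
                "week_counts_by_cluster": {
                    c: {str(w): n for w, n in counts.items()}
                    for c, counts in self.followup_plan.week_counts_by_cluster.items()
                },
                "injected_cpe": _effects_to_list(self.followup_plan.injected_cpe),
                "injected_csbp": _effects_to_list(self.followup_plan.injected_csbp),
            },
            "demographics_margins": self.demographics_margins,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        plan = data["followup_plan"]
        return cls(
            archetypes=tuple(
                ArchetypeSpec(
                    name=a["name"],
                    weekly_pe_mean=tuple(a["weekly_pe_mean"]),
                    weekly_pe_sd=tuple(a["weekly_pe_sd"]),
                    size=int(a["size"]),
                    sbp_week1_strata=tuple(a["sbp_week1_strata"]),
                    weekly_sbp_drift=tuple(a["weekly_sbp_drift"]),
                )
                for a in data["archetypes"]
            ),
            followup_plan=FollowUpPlan(
                type_counts_by_cluster={
                    c: {t: int(n) for t, n in counts.items()}
                    for c, counts in plan["type_counts_by_cluster"].items()
                },
                week_counts_by_cluster={
                    c: {int(w): int(n) for w, n in counts.items()}
                    for c, counts in plan["week_counts_by_cluster"].items()
                },
                injected_cpe=_effects_from_list(plan.get("injected_cpe", [])),
                injected_csbp=_effects_from_list(plan.get("injected_csbp", [])),
            ),
            demographics_margins=data["demographics_margins"],
            n_excluded_patients=int(data.get("n_excluded_patients", 50)),
            seed=int(data.get("seed", 0)),
            horizon_weeks=int(data.get("horizon_weeks", DEFAULT_HORIZON_WEEKS)),
            window_start=dt.date.fromisoformat(data.get("window_start", STUDY_WINDOW_START.isoformat())),
            window_end=dt.date.fromisoformat(data.get("window_end", STUDY_WINDOW_END.isoformat())),
        )

    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_config(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _effects_to_list(effects: dict) -> list[dict]:
    out = []
    for (cluster, key), value in effects.items():
        entry = {"cluster": cluster, "value": float(value)}
        if isinstance(key, str):
            entry["type"] = key
        else:
            entry["week"] = int(key)
        out.append(entry)
    return out


def _effects_from_list(entries: list[dict]) -> dict:
    out = {}
    for e in entries:
        key = e["type"] if "type" in e else int(e["week"])
        out[(e["cluster"], key)] = float(e["value"])
    return out


def default_cohort_spec(seed: int = 20160327, n_excluded_patients: int = 50) -> CohortSpec:
    """The study-structured cohort: published sizes, margins and effects."""
    archetypes = tuple(
        ArchetypeSpec(
            name=name,
            weekly_pe_mean=WEEKLY_PE_MEAN[name],
            weekly_pe_sd=WEEKLY_PE_SD[name],
            size=ARCHETYPE_SIZES[name],
            sbp_week1_strata=tuple(
                c / ARCHETYPE_SIZES[name] for c in SBP_STRATUM_COUNTS[name]
            ),
            weekly_sbp_drift=WEEKLY_SBP_DRIFT[name],
        )
        for name in ARCHETYPES
    )
    plan = FollowUpPlan(
        type_counts_by_cluster={c: dict(v) for c, v in FOLLOWUP_TYPE_COUNTS.items()},
        week_counts_by_cluster={c: dict(v) for c, v in FOLLOWUP_WEEK_COUNTS.items()},
        injected_cpe={
            (c, t): v for c, by_t in INJECTED_CPE_BY_TYPE.items() for t, v in by_t.items()
        },
        injected_csbp={
            (c, w): v for c, by_w in INJECTED_CSBP_BY_WEEK.items() for w, v in by_w.items()
        },
    )
    return CohortSpec(
        archetypes=archetypes,
        followup_plan=plan,
        demographics_margins={c: {k: dict(v) for k, v in m.items()} for c, m in DEMOGRAPHIC_MARGINS.items()},
        n_excluded_patients=n_excluded_patients,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_AGE_RANGES = {"18-40": (19, 40), "40-60": (41, 60), ">60": (61, 85)}


def _years_before(day: dt.date, years: int) -> dt.date:
    try:
        return day.replace(year=day.year - years)
    except ValueError:  # Feb 29
        return day.replace(year=day.year - years, day=28)


def _draw_count(rng, level: float, sd: float) -> int:
    x = rng.normal(level, sd) if sd > 0 else float(level)
    return int(np.floor(np.clip(x, 0.0, 7.0) + 0.5))


def _expand_margin(rng, counts: dict) -> list:
    out = [k for k, n in counts.items() for _ in range(n)]
    rng.shuffle(out)
    return out


def generate_cohort(spec: CohortSpec) -> EventLog:
    """Materialize an event log from a :class:`CohortSpec`.

    Deterministic given ``spec.seed``: identical spec => identical log.
    """
    W = spec.horizon_weeks
    ss = np.random.SeedSequence(spec.seed)
    rng_demo, rng_fu, rng_pe, rng_bp, rng_excl = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    window_days = (spec.window_end - spec.window_start).days
    demo_rows, bp_rows, fu_rows, truth_rows = [], [], [], []

    # -- patient roster & demographics (exact margins per archetype) -------
    pid_counter = 0
    patients: list[dict] = []
    for arch in spec.archetypes:
        margins = spec.demographics_margins.get(arch.name)
        if margins is not None and any(
            sum(counts.values()) != arch.size for counts in margins.values()
        ):
            raise ValueError(f"{arch.name}: demographic margins do not sum to archetype size")
        ages = _expand_margin(rng_demo, margins["age"]) if margins else ["40-60"] * arch.size
        genders = _expand_margin(rng_demo, margins["gender"]) if margins else ["male"] * arch.size
        educations = (
            _expand_margin(rng_demo, margins["education"]) if margins else ["high_school"] * arch.size
        )
        stratum_counts = largest_remainder(arch.sbp_week1_strata, arch.size)
        strata = [s for s, n in enumerate(stratum_counts) for _ in range(n)]
        rng_demo.shuffle(strata)
        for i in range(arch.size):
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            reg = spec.window_start + dt.timedelta(days=int(rng_demo.integers(0, window_days + 1)))
            lo, hi = _AGE_RANGES[ages[i]]
            age = int(rng_demo.integers(lo, hi + 1))
            birth = _years_before(reg, age) - dt.timedelta(days=int(rng_demo.integers(0, 365)))
            patients.append(
                {"pid": pid, "arch": arch, "reg": reg, "stratum": strata[i]}
            )
            demo_rows.append((pid, birth, genders[i], educations[i], reg))
            truth_rows.append((pid, arch.name))

    by_arch: dict[str, list[dict]] = {a.name: [] for a in spec.archetypes}
    for p in patients:
        by_arch[p["arch"].name].append(p)

    # -- follow-up events: week margin exact, type margin rescaled ---------
    plan = spec.followup_plan
    events: dict[tuple[str, int], str] = {}  # (pid, week) -> type
    for arch in spec.archetypes:
        members = by_arch[arch.name]
        week_counts = plan.week_counts_by_cluster.get(arch.name, {})
        slots: list[tuple[str, int]] = []
        for week in sorted(week_counts):
            n = week_counts[week]
            if not 1 <= week <= W - 1:
                raise ValueError(f"{arch.name}: follow-up week {week} outside effect-eligible range")
            if n > len(members):
                raise ValueError(
                    f"{arch.name}: {n} follow-ups in week {week} exceed the "
                    f"{len(members)} available patient-weeks"
                )
            chosen = rng_fu.choice(len(members), size=n, replace=False)
            slots.extend((members[j]["pid"], week) for j in chosen)
        types = _expand_margin(rng_fu, plan.effective_type_counts(arch.name))
        for (pid, week), ftype in zip(slots, types):
            events[(pid, week)] = ftype
            reg = next(p["reg"] for p in members if p["pid"] == pid)
            day = 7 * (week - 1) + int(rng_fu.integers(0, 7))
            fu_rows.append((pid, reg + dt.timedelta(days=day), ftype))

    # -- engagement counts, record days, SBP levels ------------------------
    for p in patients:
        arch, pid, reg = p["arch"], p["pid"], p["reg"]
        band = SBP_STRATUM_BANDS[p["stratum"]]
        sbp_level = rng_bp.uniform(band[0], band[1])
        pe_override: float | None = None
        for week in range(1, W + 1):
            level = pe_override if pe_override is not None else arch.mean_at(week)
            count = _draw_count(rng_pe, level, arch.sd_at(week))
            if week in (1, W):
                count = max(count, 1)  # selection guarantee: records early and late
            days = _record_days(rng_pe, week, count, W)
            for d in days:
                ts = dt.datetime.combine(
                    reg + dt.timedelta(days=7 * (week - 1) + d),
                    dt.time(
                        int(rng_bp.integers(6, 22)),
                        int(rng_bp.integers(0, 60)),
                        int(rng_bp.integers(0, 60)),
                    ),
                )
                sbp = float(np.clip(np.round(rng_bp.normal(sbp_level, SBP_RECORD_NOISE_SD)), 60, 260))
                dbp = float(np.clip(np.round(0.62 * sbp + rng_bp.normal(0.0, 4.0)), 40, 150))
                bp_rows.append((pid, ts, sbp, dbp))
            event_type = events.get((pid, week))
            if event_type is not None:
                pe_override = count + plan.shift_for(plan.injected_cpe, arch.name, event_type, week)
                sbp_level = sbp_level + plan.shift_for(plan.injected_csbp, arch.name, event_type, week)
            else:
                pe_override = None
                sbp_level = sbp_level + arch.drift_at(week)
            sbp_level = float(np.clip(sbp_level, 85.0, 250.0))

    # -- deliberately filter-failing patients (one rule each, round robin) --
    _generate_excluded(spec, rng_excl, demo_rows, bp_rows, truth_rows)

    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "birth_date", "gender", "education", "registration_date"]
    )
    bp_records = pd.DataFrame(bp_rows, columns=["patient_id", "timestamp", "sbp_mmhg", "dbp_mmhg"])
    followups = pd.DataFrame(fu_rows, columns=["patient_id", "date", "type"])
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "archetype"])
    return EventLog(demographics, bp_records, followups, truth=truth).validate()


def _record_days(rng, week: int, count: int, horizon: int) -> list[int]:
    """Choose ``count`` distinct weekdays (0..6), honoring selection guarantees.

    Week 1 always includes day 0 (registration-day measurement); the final
    horizon week includes at least one day >= 1, so the overall record span
    exceeds 28 days for every planted passer.
    """
    if count <= 0:
        return []
    if count >= 7:
        return list(range(7))
    if week == 1:
        rest = rng.choice(np.arange(1, 7), size=count - 1, replace=False)
        return sorted([0, *map(int, rest)])
    if week == horizon:
        anchor = int(rng.integers(1, 7))
        pool = np.array([d for d in range(7) if d != anchor])
        rest = rng.choice(pool, size=count - 1, replace=False)
        return sorted([anchor, *map(int, rest)])
    return sorted(map(int, rng.choice(7, size=count, replace=False)))


def _generate_excluded(spec: CohortSpec, rng, demo_rows, bp_rows, truth_rows) -> None:
    rules = ("age", "window", "duration")
    for i in range(spec.n_excluded_patients):
        rule = rules[i % len(rules)]
        pid = f"X{i + 1:03d}"
        window_days = (spec.window_end - spec.window_start).days
        reg = spec.window_start + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
        age = 17 if rule == "age" else int(rng.integers(35, 66))
        if rule == "window":
            reg = spec.window_start - dt.timedelta(days=int(rng.integers(10, 101)))
        birth = _years_before(reg, age) - dt.timedelta(days=int(rng.integers(0, 365)))
        demo_rows.append((pid, birth, ("male", "female")[i % 2], "high_school", reg))
        truth_rows.append((pid, "excluded"))
        if rule == "duration":
            days = [0, 3, 5, 7, 10, 12, 14, 17, 20]  # span 20 days: fails span > 28
        else:
            days = sorted(
                {0, 30}
                | {7 * (w - 1) + int(rng.integers(0, 7)) for w in range(1, spec.horizon_weeks + 1) for _ in range(3)}
            )
        for d in days:
            ts = dt.datetime.combine(
                reg + dt.timedelta(days=d),
                dt.time(int(rng.integers(6, 22)), int(rng.integers(0, 60)), int(rng.integers(0, 60))),
            )
            sbp = float(np.clip(np.round(rng.normal(130.0, SBP_RECORD_NOISE_SD)), 60, 260))
            dbp = float(np.clip(np.round(0.62 * sbp + rng.normal(0.0, 4.0)), 40, 150))
            bp_rows.append((pid, ts, sbp, dbp))
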