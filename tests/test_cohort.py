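"""Synthetic cohort generator: defaults, determinism, margins, injections."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bpengage.cohort import (
    ARCHETYPES,
    ArchetypeSpec,
    CohortSpec,
    FollowUpPlan,
    default_cohort_spec,
    generate_cohort,
    largest_remainder,
    SBP_STRATUM_COUNTS,
    FOLLOWUP_WEEK_COUNTS,
)
from bpengage.effects import bin_followups
from bpengage.eventlog import read_event_log

from .oracles import expected_weekly_count_mean


def one_archetype_spec(mean, sd, size, seed=5, plan=None, n_excluded=0, name="PEHH"):
    arch = ArchetypeSpec(
        name=name,
        weekly_pe_mean=tuple(mean),
        weekly_pe_sd=tuple(sd),
        size=size,
        sbp_week1_strata=(0.0, 1.0, 0.0, 0.0, 0.0),
        weekly_sbp_drift=(0.0, 0.0, 0.0, 0.0),
    )
    return CohortSpec(
        archetypes=(arch,),
        followup_plan=plan or FollowUpPlan({}, {}),
        demographics_margins={},
        n_excluded_patients=n_excluded,
        seed=seed,
    )


class TestDefaultSpec:
    def test_published_structure(self, default_spec):
        by_name = {a.name: a for a in default_spec.archetypes}
        assert by_name["PEHH"].weekly_pe_mean == (6.4, 6.6, 6.4, 6.3)
        assert default_spec.total_passing == 183 + 142 + 148 + 89 == 562
        week_total = sum(
            n for counts in default_spec.followup_plan.week_counts_by_cluster.values()
            for n in counts.values()
        )
        assert week_total == 680

    def test_margins_sum_to_archetype_sizes(self, default_spec):
        for arch in default_spec.archetypes:
            margins = default_spec.demographics_margins[arch.name]
            for attr, counts in margins.items():
                assert sum(counts.values()) == arch.size, (arch.name, attr)
            assert sum(SBP_STRATUM_COUNTS[arch.name]) == arch.size

    def test_effective_type_counts_match_week_totals(self, default_spec):
        plan = default_spec.followup_plan
        for name in ARCHETYPES:
            eff = plan.effective_type_counts(name)
            assert sum(eff.values()) == plan.total_events(name)
            # rescaling preserves the ranking of the raw margin
            raw = plan.type_counts_by_cluster[name]
            assert sorted(raw, key=raw.get) == sorted(eff, key=eff.get)

    def test_config_round_trip(self, default_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        default_spec.to_config(path)
        assert CohortSpec.from_config(path) == default_spec


class TestGeneration:
    def test_fixed_seed_is_byte_identical(self, default_spec, tmp_path):
        log_a = generate_cohort(default_spec)
        log_b = generate_cohort(default_cohort_spec(seed=default_spec.seed))
        assert log_a.equals(log_b)
        log_a.write(tmp_path / "a")
        log_b.write(tmp_path / "b")
        for name in ("demographics.csv", "bp_records.csv", "followups.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_demographics_row_count(self, default_log, default_spec):
        assert len(default_log.demographics) == 562 + default_spec.n_excluded_patients

    def test_write_read_round_trip(self, default_log, tmp_path):
        default_log.write(tmp_path / "cohort")
        back = read_event_log(tmp_path / "cohort")
        assert back.equals(default_log)

    def test_record_days_within_horizon(self, default_log, default_spec):
        reg = default_log.demographics.set_index("patient_id")["registration_date"]
        passers = default_log.truth.loc[default_log.truth["archetype"] != "excluded", "patient_id"]
        rec = default_log.bp_records[default_log.bp_records["patient_id"].isin(set(passers))]
        offsets = np.array(
            [(t.date() - reg.at[pid]).days for pid, t in zip(rec["patient_id"], rec["timestamp"])]
        )
        assert offsets.min() >= 0
        assert offsets.max() < 7 * default_spec.horizon_weeks

    def test_followup_margins_exact(self, default_log, default_spec):
        truth = default_log.truth.set_index("patient_id")["archetype"]
        fu = bin_followups(default_log, weeks=default_spec.horizon_weeks)
        fu["arch"] = fu["patient_id"].map(truth)
        plan = default_spec.followup_plan
        for name in ARCHETYPES:
            by_week = fu[fu["arch"] == name]["week"].value_counts().to_dict()
            assert by_week == FOLLOWUP_WEEK_COUNTS[name]
            by_type = fu[fu["arch"] == name]["type"].value_counts().to_dict()
            assert by_type == plan.effective_type_counts(name)

    def test_demographic_margins_exact(self, default_log):
        from bpengage.cohort import DEMOGRAPHIC_MARGINS
        from bpengage.trajectories import age_at

        demo = default_log.demographics.merge(default_log.truth, on="patient_id")
        demo = demo[demo["archetype"] != "excluded"]
        ages = [age_at(b, r) for b, r in zip(demo["birth_date"], demo["registration_date"])]
        demo["band"] = pd.cut(pd.Series(ages), bins=(-np.inf, 40, 60, np.inf),
                              labels=("18-40", "40-60", ">60")).astype(str).to_numpy()
        for name in ARCHETYPES:
            block = demo[demo["archetype"] == name]
            assert block["band"].value_counts().to_dict() == DEMOGRAPHIC_MARGINS[name]["age"]
            assert block["gender"].value_counts().to_dict() == DEMOGRAPHIC_MARGINS[name]["gender"]
            assert (
                block["education"].value_counts().to_dict()
                == DEMOGRAPHIC_MARGINS[name]["education"]
            )

    def test_zero_variance_full_engagement(self):
        spec = one_archetype_spec((7, 7, 7, 7), (0, 0, 0, 0), size=1)
        log = generate_cohort(spec)
        days = log.bp_records["timestamp"].map(lambda t: t.date()).nunique()
        assert days == 7 * spec.horizon_weeks  # 7 record-days every week

    def test_excess_followups_rejected(self):
        plan = FollowUpPlan({"PEHH": {"regular": 5}}, {"PEHH": {1: 5}})
        spec = one_archetype_spec((6, 6, 6, 6), (0, 0, 0, 0), size=3, plan=plan)
        with pytest.raises(ValueError, match="exceed"):
            generate_cohort(spec)

    def test_injected_cpe_shifts_following_week(self):
        """sd=0: the week after a compliance follow-up rises by the injection."""
        plan = FollowUpPlan(
            {"PELH": {"compliance": 2}},
            {"PELH": {1: 2}},
            injected_cpe={("PELH", "compliance"): 2.0},
        )
        spec = one_archetype_spec((1, 1, 1, 1), (0, 0, 0, 0), size=4, plan=plan, name="PELH")
        log = generate_cohort(spec)
        from bpengage.trajectories import extract_trajectories

        pe, _ = extract_trajectories(log)
        followed = set(log.followups["patient_id"])
        for pid in pe.index:
            assert pe.at[pid, 2] == (3 if pid in followed else 1)


class TestStatisticalStructure:
    def test_weekly_means_converge_to_analytic_law(self):
        """Large-archetype empirical weekly means match the rounded/clipped
        normal expectation (selection floor applies to first/last weeks)."""
        mean, sd, n = (1.9, 0.8, 6.4, 3.5), (1.1, 1.3, 0.9, 2.0), 5000
        spec = one_archetype_spec(mean, sd, size=n, seed=99)
        log = generate_cohort(spec)
        from bpengage.trajectories import extract_trajectories

        pe, _ = extract_trajectories(log)
        for week in range(1, 5):
            expected = expected_weekly_count_mean(mean[week - 1], sd[week - 1], floor_one=week == 1)
            tol = 3 * sd[week - 1] / np.sqrt(n)
            assert abs(pe[week].mean() - expected) < tol, f"week {week}"

    def test_excluded_patients_fail_one_rule_each(self, default_log, default_spec):
        from bpengage.trajectories import apply_inclusion_filters

        _, report = apply_inclusion_filters(default_log)
        assert len(report) == default_spec.n_excluded_patients
        assert set(report["patient_id"]).isdisjoint(
            set(default_log.truth.loc[default_log.truth["archetype"] != "excluded", "patient_id"])
        )
        counts = report["rule"].value_counts()
        assert counts.sum() == 50 and counts.min() >= 16  # round robin over 3 rules


@pytest.mark.parametrize(
    "props, total, expected",
    [
        ((1, 1, 1), 4, [2, 1, 1]),
        ((77, 80, 10), 174, [80, 83, 11]),
        ((0.5, 0.5), 7, [4, 3]),
    ],
)
def test_largest_remainder(props, total, expected):
    assert largest_remainder(props, total).tolist() == expected


def test_archetype_spec_invariants():
    with pytest.raises(ValueError, match=r"\[0, 7\]"):
        ArchetypeSpec("A", (8, 1, 1, 1), (1, 1, 1, 1), 5, (1, 0, 0, 0, 0), (0, 0, 0, 0))
    with pytest.raises(ValueError, match="sum to 1"):
        ArchetypeSpec("A", (1, 1, 1, 1), (1, 1, 1, 1), 5, (0.5, 0.2, 0, 0, 0), (0, 0, 0, 0))
    with pytest.raises(ValueError, match="unique"):
        a = ArchetypeSpec("A", (1, 1, 1, 1), (1, 1, 1, 1), 5, (1, 0, 0, 0, 0), (0, 0, 0, 0))
        CohortSpec(archetypes=(a, a), followup_plan=FollowUpPlan({}, {}), demographics_margins={})
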