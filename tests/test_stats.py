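"""Characterization statistics: chi-square, proportion z, ANOVA, post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bpengage.cohort import (
    DEMOGRAPHIC_MARGINS,
    FOLLOWUP_TYPE_COUNTS,
    FOLLOWUP_WEEK_COUNTS,
    SBP_STRATUM_COUNTS,
)
from bpengage.stats import (
    anova_two_way,
    bonferroni_pairs,
    chisq_association,
    pairwise_prop_z,
    weekly_sbp_trend,
)

CLUSTERS = ("PELL", "PEHH", "PEHL", "PELH")


def margin_table(attr):
    cats = list(DEMOGRAPHIC_MARGINS["PELL"][attr])
    return pd.DataFrame(
        {c: [DEMOGRAPHIC_MARGINS[c][attr][cat] for cat in cats] for c in CLUSTERS}, index=cats
    )


class TestChiSquare:
    def test_age_association_replicates_published_p(self):
        stat, dof, p = chisq_association(margin_table("age"))
        assert dof == 6
        assert p == pytest.approx(0.001, abs=0.0005)

    @pytest.mark.parametrize(
        "attr, expected_p",
        [("gender", 0.37), ("education", 0.45)],
    )
    def test_nonsignificant_demographics(self, attr, expected_p):
        _, _, p = chisq_association(margin_table(attr))
        assert p == pytest.approx(expected_p, abs=0.005)

    def test_followup_tables(self):
        typ = pd.DataFrame(
            {c: [FOLLOWUP_TYPE_COUNTS[c][t] for t in ("compliance", "regular", "abnormal")]
             for c in CLUSTERS},
            index=("compliance", "regular", "abnormal"),
        )
        _, _, p_type = chisq_association(typ)
        assert p_type == pytest.approx(0.02, abs=0.005)
        wk = pd.DataFrame(
            {c: [FOLLOWUP_WEEK_COUNTS[c][w] for w in (1, 2, 3, 4)] for c in CLUSTERS},
            index=(1, 2, 3, 4),
        )
        _, _, p_week = chisq_association(wk)
        assert p_week == pytest.approx(0.11, abs=0.01)

    def test_sbp_strata_highly_significant(self):
        t = pd.DataFrame({c: SBP_STRATUM_COUNTS[c] for c in CLUSTERS})
        with pytest.warns(UserWarning, match="expected count"):
            _, _, p = chisq_association(t)
        assert p < 0.001

    def test_proportional_table_is_null(self):
        t = pd.DataFrame([[10, 20], [30, 60]])
        stat, dof, p = chisq_association(t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = margin_table("age")
        s1, _, _ = chisq_association(t)
        s2, _, _ = chisq_association(t.iloc[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_association(pd.DataFrame([[0, 0], [3, 4]]))


class TestPairwiseZ:
    def test_over60_pehh_vs_pell_significant(self):
        t = margin_table("age")
        res = pairwise_prop_z(t, ">60")
        row = res[(res["cluster_a"] == "PEHH") & (res["cluster_b"] == "PELL")
                  | (res["cluster_a"] == "PELL") & (res["cluster_b"] == "PEHH")].iloc[0]
        assert row["significant"]

    def test_identical_proportions_null(self):
        t = pd.DataFrame({"A": [10, 90], "B": [10, 90]}, index=["hit", "miss"])
        res = pairwise_prop_z(t, "hit")
        assert res.iloc[0]["z"] == 0.0
        assert res.iloc[0]["p_adj"] == pytest.approx(1.0)

    def test_extreme_split_matches_closed_form(self):
        # 0/10 vs 10/10: pooled p=.5, z = 1/sqrt(.25*(2/10)) = sqrt(20)
        t = pd.DataFrame({"A": [0, 10], "B": [10, 0]}, index=["hit", "miss"])
        res = pairwise_prop_z(t, "hit")
        assert abs(res.iloc[0]["z"]) == pytest.approx(np.sqrt(20))
        assert res.iloc[0]["p_adj"] < 0.001

    def test_adjustment_monotone_and_capped(self):
        res = pairwise_prop_z(margin_table("gender"), "male")
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert (res["p_adj"] <= 1.0).all()

    def test_family_wise_error_under_null(self):
        """1,000 null replicates: any-significant rate stays near alpha."""
        rng = np.random.default_rng(123)
        false_hits = 0
        reps = 1000
        for _ in range(reps):
            hits = rng.binomial(80, 0.3, size=4)
            t = pd.DataFrame(
                {c: [h, 80 - h] for c, h in zip("ABCD", hits)}, index=["hit", "miss"]
            )
            if pairwise_prop_z(t, "hit")["significant"].any():
                false_hits += 1
        # Bonferroni guarantees FWER <= .05; allow 3 sigma of simulation noise
        assert false_hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def make_samples(rng, means: dict, n_per_cell: int, sd: float = 1.0, factor: str = "type"):
    rows = []
    for (cluster, level), mu in means.items():
        for _ in range(n_per_cell):
            rows.append((cluster, level, rng.normal(mu, sd)))
    frame = pd.DataFrame(rows, columns=["cluster", factor, "delta_pe"])
    frame["delta_sbp"] = np.nan
    return frame


class TestAnova:
    def grid(self, cluster_effects=(0, 0), level_effects=(0, 0), interaction=0.0):
        means = {}
        for ci, cluster in enumerate(("C1", "C2")):
            for li, level in enumerate(("regular", "abnormal")):
                mu = cluster_effects[ci] + level_effects[li]
                if ci == li == 0:
                    mu += interaction
                means[(cluster, level)] = mu
        return means

    def test_type3_equals_sequential_on_balanced_data(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        samples = make_samples(rng, self.grid((0.0, 1.0), (0.0, 0.5), 0.3), n_per_cell=25)
        res3 = anova_two_way(samples, response="delta_pe", factor2="type")
        data = samples.rename(columns={"delta_pe": "y"})
        seq = sm.stats.anova_lm(
            smf.ols("y ~ C(cluster, Sum) * C(Q('type'), Sum)", data=data).fit(), typ=1
        )
        assert res3.F["cluster"] == pytest.approx(seq.loc["C(cluster, Sum)", "F"])
        assert res3.F["type"] == pytest.approx(seq.loc["C(Q('type'), Sum)", "F"])
        assert res3.F["cluster:type"] == pytest.approx(
            seq.loc["C(cluster, Sum):C(Q('type'), Sum)", "F"]
        )

    def test_planted_cluster_effect_detected_without_interaction(self):
        rng = np.random.default_rng(21)
        samples = make_samples(rng, self.grid(cluster_effects=(0.0, 1.5)), n_per_cell=40)
        res = anova_two_way(samples, response="delta_pe", factor2="type")
        assert res.p["cluster"] < 0.001
        assert res.p["cluster:type"] > 0.05

    def test_constant_response_is_all_null(self):
        samples = make_samples(np.random.default_rng(0), self.grid(), n_per_cell=5, sd=0.0)
        res = anova_two_way(samples, response="delta_pe", factor2="type")
        assert all(f == 0.0 for f in res.F.values())
        assert all(p == 1.0 for p in res.p.values())

    def test_planted_interaction_power(self):
        """Effect confined to one cell (d=1, n=200/cell) is detected nearly always."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 100
        for _ in range(reps):
            samples = make_samples(rng, self.grid(interaction=1.0), n_per_cell=200)
            if anova_two_way(samples, "delta_pe", "type").p["cluster:type"] < 0.05:
                hits += 1
        assert hits / reps >= 0.95

    def test_empty_cell_named_in_error(self):
        rng = np.random.default_rng(3)
        samples = make_samples(rng, self.grid(), n_per_cell=5)
        samples = samples[~((samples["cluster"] == "C2") & (samples["type"] == "abnormal"))]
        with pytest.raises(ValueError, match="C2.*abnormal"):
            anova_two_way(samples, "delta_pe", "type")

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(4)
        samples = make_samples(rng, {("C1", "regular"): 0.0, ("C2", "regular"): 0.0}, 5)
        with pytest.raises(ValueError, match="type"):
            anova_two_way(samples, "delta_pe", "type")


class TestBonferroniPairs:
    def test_planted_effect_flags_pair(self):
        rng = np.random.default_rng(31)
        means = {(c, "compliance"): 0.0 for c in ("PELL", "PEHH", "PEHL")}
        means[("PELH", "compliance")] = 1.5
        samples = make_samples(rng, means, n_per_cell=60)
        res = bonferroni_pairs(samples, "delta_pe", "type", "compliance")
        flagged = res[res["significant"]]
        assert any(
            {"PELH", "PELL"} == {r["cluster_a"], r["cluster_b"]}
            for _, r in flagged.iterrows()
        )

    def test_two_clusters_single_comparison_unadjusted(self):
        rng = np.random.default_rng(5)
        samples = make_samples(rng, {("A", "regular"): 0, ("B", "regular"): 0}, 10)
        res = bonferroni_pairs(samples, "delta_pe", "type", "regular")
        assert len(res) == 1
        assert res.iloc[0]["p_adj"] == pytest.approx(res.iloc[0]["p_raw"])

    def test_adjusted_p_monotone_and_capped(self):
        rng = np.random.default_rng(6)
        samples = make_samples(rng, {(c, "regular"): 0 for c in "ABCD"}, 15)
        res = bonferroni_pairs(samples, "delta_pe", "type", "regular")
        ok = res["note"] == ""
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p_raw"] - 1e-15).all()
        assert (res.loc[ok, "p_adj"] <= 1.0).all()

    def test_small_cluster_skipped_with_notice(self):
        rng = np.random.default_rng(7)
        samples = make_samples(rng, {("A", "regular"): 0, ("B", "regular"): 0}, 10)
        samples = pd.concat(
            [samples, pd.DataFrame([("C", "regular", 0.1, np.nan)], columns=samples.columns)]
        )
        res = bonferroni_pairs(samples, "delta_pe", "type", "regular")
        assert (res["note"].str.contains("skipped")).sum() == 1

    def test_family_wise_error_under_null(self):
        rng = np.random.default_rng(77)
        false_hits = 0
        reps = 500
        for _ in range(reps):
            samples = make_samples(rng, {(c, "regular"): 0.0 for c in "ABCD"}, 10)
            if bonferroni_pairs(samples, "delta_pe", "type", "regular")["significant"].any():
                false_hits += 1
        assert false_hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_warns_without_significant_omnibus(self):
        rng = np.random.default_rng(8)
        samples = make_samples(rng, {("A", "regular"): 0, ("B", "regular"): 0}, 10)
        with pytest.warns(UserWarning, match="omnibus"):
            bonferroni_pairs(samples, "delta_pe", "type", "regular", omnibus_significant=False)


class TestWeeklyTrend:
    @staticmethod
    def sbp_frame(rng, n, drift):
        base = rng.normal(135, 8, size=n)
        data = {w: base + drift * (w - 1) + rng.normal(0, 2, size=n) for w in (1, 2, 3, 4)}
        frame = pd.DataFrame(data, index=[f"P{i}" for i in range(n)])
        frame.index.name = "patient_id"
        return frame

    def test_planted_drift_detected(self):
        rng = np.random.default_rng(9)
        sbp = self.sbp_frame(rng, n=150, drift=-3.0)
        labels = pd.Series("PEHH", index=sbp.index)
        res = weekly_sbp_trend(sbp, labels)
        row = res[(res["week_a"] == 1) & (res["week_b"] == 2)].iloc[0]
        assert row["significant"] and row["mean_change"] < 0

    def test_null_drift_rate_bounded(self):
        rng = np.random.default_rng(10)
        false_hits = 0
        reps = 300
        for _ in range(reps):
            sbp = self.sbp_frame(rng, n=40, drift=0.0)
            labels = pd.Series("X", index=sbp.index)
            if weekly_sbp_trend(sbp, labels)["significant"].any():
                false_hits += 1
        assert false_hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_week_rejected(self):
        sbp = self.sbp_frame(np.random.default_rng(1), 10, 0.0)
        with pytest.raises(ValueError):
            weekly_sbp_trend(sbp, pd.Series("X", index=sbp.index), weeks=(1,))

    def test_insufficient_pairs_skipped(self):
        sbp = pd.DataFrame(
            {1: [130.0, 131.0], 2: [np.nan, np.nan], 3: [128.0, 126.0], 4: [np.nan, 125.0]},
            index=["P1", "P2"],
        )
        res = weekly_sbp_trend(sbp, pd.Series("X", index=sbp.index))
        skipped = res[res["note"] != ""]
        assert {(1, 2), (2, 3), (2, 4), (1, 4), (3, 4)} >= {
            (r["week_a"], r["week_b"]) for _, r in skipped.iterrows()
        }
        assert len(skipped) >= 3
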