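"""Cluster characterization statistics.

Pearson chi-square association tests on cluster-by-category contingency
tables, pairwise two-proportion z tests with Bonferroni adjustment,
two-way fixed-effects ANOVA (Type III sums of squares, matching the
convention of mainstream commercial statistics packages for unbalanced
designs) on follow-up effect samples, Bonferroni pairwise t post-hocs,
and paired weekly SBP trend comparisons.  The significance level is .05
throughout; Bonferroni families are the pairwise comparisons within one
post-hoc analysis, never across analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.05


@dataclass
class AnovaResult:
    factors: tuple[str, str]
    F: dict[str, float]
    p: dict[str, float]
    posthoc: list = field(default_factory=list)


def chisq_association(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c table.

    Emits a ``UserWarning`` when any expected count is below 5; raises on
    zero-margin rows/columns or degenerate shapes.
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least 2 rows and 2 columns")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero-margin row or column")
    stat, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) have expected count < 5; "
            "the chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    return float(stat), int(dof), float(p)


def pairwise_prop_z(table: pd.DataFrame, row: str) -> pd.DataFrame:
    """Pairwise two-proportion z tests for one category row across clusters.

    For each unordered cluster pair the pooled-variance z statistic for
    the difference in the row's within-cluster proportion is computed,
    two-sided p values are Bonferroni-multiplied by the number of pairs,
    and flags are set at adjusted p < .05.
    """
    if row not in table.index:
        raise KeyError(f"row {row!r} not in table")
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("every cluster column needs a positive total")
    hits = table.loc[row]
    clusters = list(table.columns)
    pairs = list(itertools.combinations(clusters, 2))
    rows = []
    for a, b in pairs:
        x1, n1, x2, n2 = hits[a], totals[a], hits[b], totals[b]
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = 0.0 if se == 0 else float((x1 / n1 - x2 / n2) / se)
        p_raw = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * len(pairs))
        rows.append((a, b, z, p_raw, p_adj, p_adj < ALPHA))
    return pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "z", "p_raw", "p_adj", "significant"]
    )


def anova_two_way(
    samples: pd.DataFrame, response: str = "delta_pe", factor2: str = "type"
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on effect samples.

    Factors are ``cluster`` and ``factor2`` (``"type"`` or ``"week"``);
    Type III sums of squares with sum-to-zero contrasts are used so the
    tests are well defined on unbalanced data.  An empty cluster x level
    cell makes the interaction unidentifiable and raises with the cell
    named.  An all-constant response returns F = 0, p = 1 for every
    effect.
    """
    data = samples[["cluster", factor2, response]].dropna().rename(columns={response: "y"})
    for factor in ("cluster", factor2):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels with data")
    cells = data.groupby(["cluster", factor2]).size()
    full = itertools.product(data["cluster"].unique(), data[factor2].unique())
    for cell in full:
        if cell not in cells.index:
            raise ValueError(f"empty design cell {cell}: model is unidentifiable")

    effects = ["cluster", factor2, f"cluster:{factor2}"]
    if np.ptp(data["y"].to_numpy()) == 0:
        return AnovaResult(
            factors=("cluster", factor2),
            F={e: 0.0 for e in effects},
            p={e: 1.0 for e in effects},
        )

    model = smf.ols(f"y ~ C(cluster, Sum) * C(Q('{factor2}'), Sum)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    name_map = {
        "C(cluster, Sum)": "cluster",
        f"C(Q('{factor2}'), Sum)": factor2,
        f"C(cluster, Sum):C(Q('{factor2}'), Sum)": f"cluster:{factor2}",
    }
    F, p = {}, {}
    for raw, name in name_map.items():
        F[name] = float(tab.loc[raw, "F"])
        p[name] = float(tab.loc[raw, "PR(>F)"])
    return AnovaResult(factors=("cluster", factor2), F=F, p=p)


def bonferroni_pairs(
    samples: pd.DataFrame,
    response: str,
    factor2: str,
    level,
    omnibus_significant: bool | None = None,
) -> pd.DataFrame:
    """All-cluster-pair t comparisons within one ``factor2`` level.

    Two-sample equal-variance t tests; p values are multiplied by the
    number of comparisons performed and capped at 1, flagged at .05.
    Clusters with fewer than 2 samples in the level are skipped (noted in
    the ``note`` column of a sentinel row).  ``omnibus_significant=False``
    warns (post-hocs after a non-significant omnibus test) but proceeds.
    """
    if omnibus_significant is False:
        warnings.warn(
            "running Bonferroni post-hocs without a significant omnibus effect",
            UserWarning,
            stacklevel=2,
        )
    sub = samples[samples[factor2] == level][["cluster", response]].dropna()
    groups = {c: g[response].to_numpy() for c, g in sub.groupby("cluster")}
    usable = sorted(c for c, v in groups.items() if len(v) >= 2)
    skipped = sorted(set(groups) - set(usable))
    pairs = list(itertools.combinations(usable, 2))
    rows = []
    for a, b in pairs:
        t, p_raw = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        p_adj = min(1.0, float(p_raw) * len(pairs))
        rows.append((a, b, float(t), float(p_raw), p_adj, p_adj < ALPHA, ""))
    for c in skipped:
        rows.append((c, None, np.nan, np.nan, np.nan, False, f"cluster {c!r} has <2 samples; skipped"))
    return pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "t", "p_raw", "p_adj", "significant", "note"]
    )


def weekly_sbp_trend(
    sbp: pd.DataFrame, labels: pd.Series | dict, weeks: tuple[int, ...] = (1, 2, 3, 4)
) -> pd.DataFrame:
    """Per-cluster paired comparisons of weekly mean SBP between weeks.

    For every cluster and unordered week pair, a paired t test on the
    patients with both weeks present, Bonferroni-adjusted over the week
    pairs within the cluster.  Pairs with fewer than 2 complete patients
    are skipped with a note.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if len(weeks) < 2:
        raise ValueError("need at least 2 weeks to compare")
    pairs = list(itertools.combinations(weeks, 2))
    rows = []
    for cluster in sorted(labels.dropna().unique()):
        members = labels.index[labels == cluster]
        block = sbp.loc[sbp.index.intersection(members)]
        for w1, w2 in pairs:
            both = block[[w1, w2]].dropna()
            if len(both) < 2:
                rows.append(
                    (cluster, w1, w2, len(both), np.nan, np.nan, np.nan, np.nan, False,
                     "fewer than 2 patients with both weeks; skipped")
                )
                continue
            t, p_raw = sps.ttest_rel(both[w1], both[w2])
            p_adj = min(1.0, float(p_raw) * len(pairs))
            rows.append(
                (cluster, w1, w2, len(both), float(both[w2].mean() - both[w1].mean()),
                 float(t), float(p_raw), p_adj, p_adj < ALPHA, "")
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "week_a", "week_b", "n", "mean_change", "t", "p_raw", "p_adj",
                 "significant", "note"],
    )


def crosstab(categories: pd.Series, clusters: pd.Series) -> pd.DataFrame:
    """Category-by-cluster count table over the shared patient index."""
    joined = pd.DataFrame({"category": categories, "cluster": clusters}).dropna()
    return pd.crosstab(joined["category"], joined["cluster"])
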