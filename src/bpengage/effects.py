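"""Follow-up effect estimation: change in engagement and SBP.

For every follow-up event in week *i*, the effect sample is the change
from the event week to the week after:

    delta_pe  = PE[i+1]  - PE[i]        (days/week)
    delta_sbp = SBP[i+1] - SBP[i]       (mmHg, missing-propagating)

The published estimators CPE and CSBP are the stratum means of these
samples over the N follow-up events in the stratum (cluster x follow-up
type, or cluster x event week) — every follow-up contributes a sample, so
a patient followed up twice contributes two.  Events in the final horizon
week have no "week after" and are dropped (counted in the return).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .eventlog import EventLog


def bin_followups(log: EventLog, weeks: int = 5) -> pd.DataFrame:
    """Attribute each follow-up to a 1-based week bin after registration.

    Uses the same half-open ``[7(w-1), 7w)`` day bins as trajectory
    extraction; events outside weeks ``1..weeks`` are dropped.
    Returns columns ``patient_id, week, type``.
    """
    reg = log.demographics.set_index("patient_id")["registration_date"]
    fu = log.followups.copy()
    if fu.empty:
        return pd.DataFrame(columns=["patient_id", "week", "type"])
    offsets = [(d - reg.at[pid]).days for pid, d in zip(fu["patient_id"], fu["date"])]
    fu["week"] = [o // 7 + 1 if 0 <= o < 7 * weeks else -1 for o in offsets]
    fu = fu[fu["week"] > 0]
    return fu[["patient_id", "week", "type"]].reset_index(drop=True)


def effect_samples(
    pe: pd.DataFrame,
    sbp: pd.DataFrame,
    followups: pd.DataFrame,
    labels: pd.Series | dict,
) -> tuple[pd.DataFrame, int]:
    """One effect sample per follow-up event.

    Parameters
    ----------
    pe, sbp : weekly trajectories indexed by patient_id (columns = weeks).
    followups : ``patient_id, week, type`` rows (see :func:`bin_followups`).
    labels : patient_id -> cluster label (archetype name or index).

    Returns ``(samples, n_dropped)`` where samples has columns
    ``patient_id, cluster, type, week, delta_pe, delta_sbp`` and
    ``n_dropped`` counts events in the final horizon week (no week after).
    ``delta_sbp`` is missing whenever either weekly SBP mean is missing;
    ``delta_pe`` is always present.  An event for a patient without a
    trajectory raises ``KeyError``.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    horizon = max(pe.columns)
    rows, dropped = [], 0
    for pid, week, ftype in followups[["patient_id", "week", "type"]].itertuples(index=False):
        if pid not in pe.index:
            raise KeyError(f"follow-up event for patient {pid!r} without a trajectory")
        if week + 1 > horizon:
            dropped += 1
            continue
        delta_pe = int(pe.at[pid, week + 1]) - int(pe.at[pid, week])
        s0, s1 = sbp.at[pid, week], sbp.at[pid, week + 1]
        delta_sbp = float(s1 - s0) if pd.notna(s0) and pd.notna(s1) else np.nan
        rows.append((pid, labels.get(pid), ftype, week, delta_pe, delta_sbp))
    samples = pd.DataFrame(
        rows, columns=["patient_id", "cluster", "type", "week", "delta_pe", "delta_sbp"]
    )
    return samples, dropped


def aggregate_effects(
    samples: pd.DataFrame, by: str = "type", response: str = "delta_pe"
) -> pd.DataFrame:
    """Stratum estimates: n, mean, sd per (cluster x ``by``).

    ``by`` is ``"type"`` or ``"week"``; ``response`` is ``"delta_pe"``
    (CPE, days/week) or ``"delta_sbp"`` (CSBP, mmHg).  ``n`` counts the
    non-missing samples entering the mean; the sd uses the n-1 denominator
    and is missing for n < 2.  Strata whose responses are all missing
    report their raw event count with a missing mean.
    """
    if by not in ("type", "week"):
        raise ValueError("by must be 'type' or 'week'")
    if samples.empty:
        raise ValueError("no effect samples to aggregate")

    def _agg(group: pd.DataFrame) -> pd.Series:
        vals = group[response].dropna()
        return pd.Series(
            {
                "n": int(len(vals)) if len(vals) else int(len(group)),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) >= 2 else np.nan,
            }
        )

    out = (
        samples.groupby(["cluster", by], sort=True, dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def stratum_estimate(table: pd.DataFrame, cluster, key, by: str = "type") -> pd.Series:
    """Convenience lookup of one stratum row from :func:`aggregate_effects`."""
    row = table[(table["cluster"] == cluster) & (table[by] == key)]
    if row.empty:
        raise KeyError(f"no stratum ({cluster!r}, {key!r})")
    return row.iloc[0]
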