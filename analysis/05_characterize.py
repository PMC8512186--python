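#!/usr/bin/env python
"""Characterize the clusters: chi-square tables, ANOVA and post-hocs.

Reports the association of demographics, first-week SBP strata and
follow-up counts with cluster membership; two-way ANOVA (cluster x
type/week) on the follow-up effect samples with Bonferroni pairwise
post-hocs; and paired weekly SBP trend comparisons per cluster.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bpengage import apply_inclusion_filters, read_event_log
from bpengage.effects import bin_followups, effect_samples
from bpengage.workflow import characterization_report, read_trajectories, _jsonable


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--trajectories", type=Path, default=Path("results/trajectories.csv"))
    parser.add_argument("--clusters", type=Path, default=Path("results/clusters.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/characterization_report.json"))
    args = parser.parse_args()

    log = read_event_log(args.cohort)
    included, _ = apply_inclusion_filters(log)
    pe, sbp = read_trajectories(args.trajectories)
    labels = pd.read_csv(args.clusters).set_index("patient_id")["archetype_label"]
    samples, _ = effect_samples(pe, sbp, bin_followups(included), labels)

    report = characterization_report(included, pe, sbp, samples, labels)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(_jsonable(report), indent=2))

    print("chi-square association with cluster membership:")
    for name, entry in report["contingency"].items():
        if "p" in entry:
            print(f"  {name:<14} chi2={entry['chi2']:.1f} df={entry['df']} p={entry['p']:.3g}")
        else:
            print(f"  {name:<14} skipped ({entry['error']})")
    print("two-way ANOVA on effect samples:")
    for key, entry in report["anova"].items():
        if "F" in entry:
            terms = ", ".join(f"{t}: F={entry['F'][t]:.2f} p={entry['p'][t]:.3g}" for t in entry["F"])
            print(f"  {key:<22} {terms}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
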