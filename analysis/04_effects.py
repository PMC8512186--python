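#!/usr/bin/env python
"""Estimate follow-up effects: change in engagement (CPE) and SBP (CSBP).

For every follow-up event, the change from the event week to the next
week is one sample; samples are averaged per cluster x follow-up type and
per cluster x event week.
"""

import argparse
from pathlib import Path

import pandas as pd

from bpengage import apply_inclusion_filters, read_event_log
from bpengage.effects import aggregate_effects, bin_followups, effect_samples
from bpengage.workflow import read_trajectories


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--trajectories", type=Path, default=Path("results/trajectories.csv"))
    parser.add_argument("--clusters", type=Path, default=Path("results/clusters.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    log = read_event_log(args.cohort)
    included, _ = apply_inclusion_filters(log)
    pe, sbp = read_trajectories(args.trajectories)
    labels = pd.read_csv(args.clusters).set_index("patient_id")["archetype_label"]

    followups = bin_followups(included)
    samples, dropped = effect_samples(pe, sbp, followups, labels)
    print(f"{len(samples)} effect samples from {len(followups)} follow-ups "
          f"({dropped} final-week events dropped)")

    for by in ("type", "week"):
        frames = []
        for response in ("delta_pe", "delta_sbp"):
            t = aggregate_effects(samples, by=by, response=response)
            t = t.rename(columns={c: f"{c}_{response}" for c in ("n", "mean", "sd")})
            frames.append(t.set_index(["cluster", by]))
        table = pd.concat(frames, axis=1).reset_index()
        path = args.out / f"effects_by_{by}.csv"
        table.to_csv(path, index=False)
        print(f"wrote {path}")

    cpe = aggregate_effects(samples, by="type", response="delta_pe")
    headline = cpe[(cpe["cluster"] == "PELH") & (cpe["type"] == "compliance")]
    if len(headline):
        row = headline.iloc[0]
        print(f"headline: CPE(PELH, compliance) = {row['mean']:+.2f} days/week "
              f"(SD {row['sd']:.2f}, N={row['n']})")


if __name__ == "__main__":
    main()
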