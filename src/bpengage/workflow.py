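"""End-to-end pipeline: simulate -> extract -> cluster -> effects -> characterize.

All randomness flows from one master seed: stage substreams (cohort
generation, clustering restarts) are derived from it, so re-running with
an identical :class:`RunConfig` reproduces byte-identical artifacts.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .cluster import ClusterNamingError, kmeans_dtw, name_clusters, select_k
from .effects import aggregate_effects, bin_followups, effect_samples
from .eventlog import EventLog, read_event_log
from .stats import (
    anova_two_way,
    bonferroni_pairs,
    chisq_association,
    crosstab,
    pairwise_prop_z,
    weekly_sbp_trend,
)
from .trajectories import age_at, apply_inclusion_filters, extract_trajectories, write_trajectories

log = logging.getLogger("bpengage")

SBP_BAND_EDGES = (120.0, 140.0, 160.0, 180.0)
SBP_BAND_LABELS = ("<120", "120-139", "140-159", "160-179", ">=180")
AGE_BAND_EDGES = (40, 60)
AGE_BAND_LABELS = ("18-40", "40-60", ">60")


@dataclass
class RunConfig:
    """Pipeline configuration; ``input`` is "synthetic" or an event-log directory."""

    out_dir: str
    seed: int
    input: str = "synthetic"
    weeks: int = 5  # internal horizon
    analysis_weeks: int = 4  # weeks entering clustering
    k_range: tuple[int, int] = (3, 7)
    n_init: int = 10
    objective: str = "squared"  # clustering local cost: "squared" (classical) or "abs"
    centroid: str = "dba"  # "dba" or "medoid"
    strict_4week_mode: bool = False  # drop week-4 follow-ups instead of using week-5 data
    n_excluded_patients: int = 50

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("cohort", "cluster", "select", "extra")
        return {n: int(s) % (2**31) for n, s in zip(names, state)}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    return obj


def run_pipeline(cfg: RunConfig, cohort_spec: CohortSpec | None = None) -> Path:
    """Run every stage and write all artifacts under ``cfg.out_dir``.

    Returns the artifact directory.  Any stage failure is re-raised with
    the stage name prepended.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    manifest: dict = {
        "config": _jsonable(asdict(cfg)),
        "stage_seeds": seeds,
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("simulate/load"):
        if cfg.input == "synthetic":
            spec = cohort_spec if cohort_spec is not None else default_cohort_spec(
                seed=seeds["cohort"], n_excluded_patients=cfg.n_excluded_patients
            )
            if cohort_spec is None:
                spec = spec.with_seed(seeds["cohort"])
            event_log = generate_cohort(spec)
            cohort_dir = out / "cohort"
            event_log.write(cohort_dir)
            spec.to_config(cohort_dir / "cohort_spec.yaml")
        else:
            event_log = read_event_log(cfg.input)
        manifest["stages"]["input"] = {"patients": int(len(event_log.demographics))}

    with stage("extract"):
        included, exclusions = apply_inclusion_filters(event_log)
        pe, sbp = extract_trajectories(included, weeks=cfg.weeks)
        write_trajectories(pe, sbp, out / "trajectories.csv")
        exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"]["extract"] = {
            "included": int(len(pe)),
            "excluded": {rule: int(n) for rule, n in exclusions["rule"].value_counts().items()},
        }

    with stage("cluster"):
        X = pe[list(range(1, cfg.analysis_weeks + 1))]
        selection = select_k(
            X, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=seeds["cluster"], n_init=cfg.n_init, objective=cfg.objective, centroid=cfg.centroid,
        )
        result = kmeans_dtw(
            X, selection.best_k, seed=seeds["cluster"], n_init=cfg.n_init,
            objective=cfg.objective, centroid=cfg.centroid,
        )
        try:
            names = name_clusters(result)
            naming_failed = False
        except ClusterNamingError as err:
            log.warning("cluster naming failed: %s", err)
            names = {c: f"cluster_{c}" for c in range(result.k)}
            naming_failed = True
        labels = pd.Series(
            [names[c] for c in result.labels], index=pe.index, name="archetype"
        )
        pd.DataFrame(
            {
                "patient_id": pe.index,
                "cluster_index": result.labels,
                "archetype_label": labels.to_numpy(),
            }
        ).to_csv(out / "clusters.csv", index=False)
        (out / "model.json").write_text(
            json.dumps(
                _jsonable(
                    {
                        "k": result.k,
                        "centroids": result.centroids,
                        "cluster_names": names,
                        "silhouette": result.silhouette,
                        "silhouette_by_k": selection.silhouette_by_k,
                        "best_k": selection.best_k,
                        "inertia": result.inertia,
                        "seed": result.seed,
                        "n_init": result.n_init,
                        "naming_failed": naming_failed,
                    }
                ),
                indent=2,
            )
        )
        manifest["stages"]["cluster"] = {
            "best_k": selection.best_k,
            "sizes": {names[c]: int(n) for c, n in enumerate(result.cluster_sizes())},
            "naming_failed": naming_failed,
        }

    with stage("effects"):
        horizon = cfg.analysis_weeks if cfg.strict_4week_mode else cfg.weeks
        fu = bin_followups(included, weeks=horizon)
        samples, dropped = effect_samples(
            pe[list(range(1, horizon + 1))], sbp[list(range(1, horizon + 1))], fu, labels
        )
        tables = {}
        for by in ("type", "week"):
            frames = []
            for response, unit in (("delta_pe", "days/week"), ("delta_sbp", "mmHg")):
                t = aggregate_effects(samples, by=by, response=response)
                t = t.rename(
                    columns={"n": f"n_{response}", "mean": f"mean_{response}", "sd": f"sd_{response}"}
                )
                frames.append(t.set_index(["cluster", by]))
            tables[by] = pd.concat(frames, axis=1).reset_index()
            path = out / f"effects_by_{by}.csv"
            with open(path, "w") as fh:
                fh.write("# delta_pe in days/week (CPE); delta_sbp in mmHg (CSBP); sd uses n-1\n")
                tables[by].to_csv(fh, index=False)
        manifest["stages"]["effects"] = {
            "samples": int(len(samples)),
            "dropped_final_week_events": int(dropped),
        }

    with stage("characterize"):
        report = characterization_report(included, pe, sbp, samples, labels)
        (out / "characterization_report.json").write_text(json.dumps(_jsonable(report), indent=2))
        manifest["stages"]["characterize"] = {"tables": list(report["contingency"].keys())}

    manifest["artifact_hashes"] = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()
        for name in ("clusters.csv", "trajectories.csv", "effects_by_type.csv", "effects_by_week.csv")
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return out


def characterization_report(
    included: EventLog,
    pe: pd.DataFrame,
    sbp: pd.DataFrame,
    samples: pd.DataFrame,
    labels: pd.Series,
) -> dict:
    """All cluster-characterization tables and tests as one JSON-able dict."""
    demo = included.demographics.set_index("patient_id")
    ages = pd.Series(
        [age_at(b, r) for b, r in zip(demo["birth_date"], demo["registration_date"])],
        index=demo.index,
    )
    age_band = pd.cut(
        ages, bins=(-np.inf, *AGE_BAND_EDGES, np.inf), labels=AGE_BAND_LABELS, right=True
    ).astype(str)
    sbp_band = pd.cut(
        sbp[1], bins=(-np.inf, *SBP_BAND_EDGES, np.inf), labels=SBP_BAND_LABELS, right=False
    ).astype(str)
    fu = bin_followups(included)
    fu_labels = fu["patient_id"].map(labels)

    contingency = {
        "age": crosstab(age_band, labels),
        "gender": crosstab(demo["gender"], labels),
        "education": crosstab(demo["education"], labels),
        "sbp_week1": crosstab(sbp_band, labels),
        "followup_type": pd.crosstab(fu["type"], fu_labels),
        "followup_week": pd.crosstab(fu["week"], fu_labels),
    }
    report: dict = {"contingency": {}, "anova": {}, "posthoc": {}, "sbp_trend": None}
    for name, table in contingency.items():
        entry = {
            "table": {str(r): {str(c): int(v) for c, v in row.items()} for r, row in table.iterrows()}
        }
        try:
            stat, dof, p = chisq_association(table)
            entry.update({"chi2": stat, "df": dof, "p": p})
        except ValueError as err:  # degenerate table (e.g. a constant attribute)
            entry["error"] = str(err)
        if entry.get("p", 1.0) < 0.05 and table.shape[1] >= 2:
            entry["pairwise_z"] = {
                str(row): pairwise_prop_z(table, row).to_dict(orient="records")
                for row in table.index
            }
        report["contingency"][name] = entry

    for response in ("delta_pe", "delta_sbp"):
        for factor2 in ("type", "week"):
            key = f"{response}_by_{factor2}"
            try:
                res = anova_two_way(samples, response=response, factor2=factor2)
                report["anova"][key] = {"F": res.F, "p": res.p}
                omnibus = bool(res.p["cluster"] < 0.05)
            except ValueError as err:  # sparse design (e.g. an empty cell)
                report["anova"][key] = {"error": str(err)}
                omnibus = None
            levels = sorted(samples[factor2].dropna().unique())
            report["posthoc"][key] = {
                str(level): bonferroni_pairs(
                    samples, response, factor2, level, omnibus_significant=omnibus
                ).to_dict(orient="records")
                for level in levels
            }

    report["sbp_trend"] = weekly_sbp_trend(sbp, labels).to_dict(orient="records")
    return report


def read_trajectories(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back trajectories.csv into the (pe, sbp) frame pair."""
    frame = pd.read_csv(path, index_col="patient_id")
    pe_cols = [c for c in frame.columns if c.startswith("pe_w")]
    sbp_cols = [c for c in frame.columns if c.startswith("sbp_w")]
    pe = frame[pe_cols].rename(columns=lambda c: int(c[4:])).astype(int)
    sbp = frame[sbp_cols].rename(columns=lambda c: int(c[5:]))
    return pe, sbp
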