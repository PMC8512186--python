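#!/usr/bin/env python
"""Cluster engagement trajectories: DTW k-means with silhouette selection.

Scans k = 3..7, keeps the silhouette-maximizing k, clusters at that k and
names the clusters by centroid shape (PELL / PEHH / PEHL / PELH).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bpengage import kmeans_dtw, name_clusters, select_k
from bpengage.workflow import read_trajectories, _jsonable


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trajectories", type=Path, default=Path("results/trajectories.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-init", type=int, default=10)
    args = parser.parse_args()

    pe, _ = read_trajectories(args.trajectories)
    X = pe[[1, 2, 3, 4]]
    selection = select_k(X, k_range=range(3, 8), seed=args.seed, n_init=args.n_init)
    print("silhouette by k:", {k: round(v, 3) for k, v in selection.silhouette_by_k.items()})
    print(f"-> best k = {selection.best_k}")

    result = kmeans_dtw(X, selection.best_k, seed=args.seed, n_init=args.n_init)
    names = name_clusters(result)
    labels = [names[c] for c in result.labels]
    for c in range(result.k):
        n = int((result.labels == c).sum())
        print(f"  {names[c]}: n={n}, centroid={[round(float(v), 1) for v in result.centroids[c]]}")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"patient_id": pe.index, "cluster_index": result.labels, "archetype_label": labels}
    ).to_csv(args.out / "clusters.csv", index=False)
    (args.out / "model.json").write_text(
        json.dumps(
            _jsonable(
                {
                    "k": result.k,
                    "best_k": selection.best_k,
                    "silhouette_by_k": selection.silhouette_by_k,
                    "silhouette": result.silhouette,
                    "centroids": result.centroids,
                    "cluster_names": names,
                    "seed": result.seed,
                    "n_init": result.n_init,
                }
            ),
            indent=2,
        )
    )
    print(f"wrote {args.out}/clusters.csv and model.json")


if __name__ == "__main__":
    main()
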