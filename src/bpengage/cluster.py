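"""K-means clustering of engagement trajectories under DTW.

Lloyd-style iteration: points are assigned to the nearest centroid by DTW
and centroids are refit by DTW barycenter averaging (DBA: a fixed 10 inner
alignment/average iterations, each re-aligning members to the centroid and
replacing every centroid coordinate by the weighted mean of the values
aligned to it).  The best of ``n_init`` seeded restarts by inertia is
returned.

As in ordinary Euclidean k-means — whose objective is the sum of *squared*
distances while reported distances are unsquared — the clustering
objective here uses the squared local cost (under which the alignment-mean
DBA update descends), and the silhouette is evaluated on the package's
standard absolute-cost DTW distance matrix.  The barycenter step is
additionally descent-safeguarded (it never returns a centroid costlier
than the one it started from), so the inertia recorded after each
assignment step is non-increasing within a restart.  ``objective="abs"``
switches the optimized cost to the absolute one; ``centroid="medoid"``
replaces DBA with the member minimizing total within-cluster distance, for
sensitivity analysis.

Model selection maximizes the mean silhouette of the DTW distance matrix
over a range of cluster counts (ties break toward the smallest count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import DistanceMatrix, batch_dtw, dtw_path, _as_matrix

ARCHETYPE_LABELS = ("PELL", "PEHH", "PEHL", "PELH")

#: Week-1 centroid level (days/week) separating "started high" from
#: "started low" archetypes.
HIGH_WEEK1_THRESHOLD = 4.0


class ClusterNamingError(RuntimeError):
    """Raised when centroids cannot be bijectively mapped to archetypes."""


@dataclass
class ClusteringResult:
    k: int
    ids: list
    labels: np.ndarray  # per-patient cluster index in {0..k-1}
    centroids: np.ndarray  # (k, L)
    inertia: float  # sum of DTW distances to assigned centroids
    silhouette: float
    seed: int
    n_init: int
    inertia_history: list[float] = field(default_factory=list, repr=False)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ModelSelection:
    k_range: tuple[int, ...]
    silhouette_by_k: dict[int, float]
    best_k: int

    def __post_init__(self) -> None:
        best = min(
            (k for k in self.silhouette_by_k),
            key=lambda k: (-self.silhouette_by_k[k], k),
        )
        if best != self.best_k:
            raise ValueError("best_k is not the silhouette argmax")


def _barycenter(members, weights, init, squared: bool, n_iter: int = 10) -> np.ndarray:
    """DBA barycenter of ``members``, warm-started at ``init``.

    The alignment-mean update minimizes the squared alignment cost; under
    the absolute local cost it may occasionally overshoot, so the best
    iterate by actual within-cluster DTW cost is returned and is never
    worse than ``init`` — which makes the outer Lloyd inertia monotone.
    """
    c = np.asarray(init, dtype=float).copy()
    L = c.size

    def cost(cc: np.ndarray) -> float:
        return float((weights * batch_dtw(members, cc[None, :], squared=squared)[:, 0]).sum())

    best_c, best_cost = c.copy(), cost(c)
    for _ in range(n_iter):
        vals: list[list[float]] = [[] for _ in range(L)]
        ws: list[list[float]] = [[] for _ in range(L)]
        for s, w in zip(members, weights):
            _, path = dtw_path(c, s, squared=squared)
            for i, j in path:
                vals[i].append(s[j])
                ws[i].append(w)
        new = np.array([np.average(v, weights=w) for v, w in zip(vals, ws)])
        new_cost = cost(new)
        if new_cost < best_cost:
            best_c, best_cost = new.copy(), new_cost
        if np.allclose(new, c):
            break
        c = new
    return best_c


def _kmeanspp_init(rng, du: np.ndarray, counts: np.ndarray, k: int) -> list[int]:
    """k-means++ style seeding over distinct trajectories (without replacement)."""
    u = du.shape[0]
    probs = counts / counts.sum()
    chosen = [int(rng.choice(u, p=probs))]
    for _ in range(1, k):
        dmin = du[:, chosen].min(axis=1)
        w = counts * dmin**2
        if w.sum() <= 0:
            pool = [i for i in range(u) if i not in chosen]
            chosen.append(int(rng.choice(pool)))
        else:
            chosen.append(int(rng.choice(u, p=w / w.sum())))
    return chosen


def _medoid(members_idx: np.ndarray, counts: np.ndarray, du: np.ndarray) -> int:
    """Index (into ``du``) of the member minimizing total weighted distance."""
    block = du[np.ix_(members_idx, members_idx)]
    return int(members_idx[np.argmin(block @ counts[members_idx])])


def _lloyd(uniq, counts, du, k, rng, squared, centroid, max_iter):
    centroids = uniq[_kmeanspp_init(rng, du, counts, k)].astype(float)
    u = uniq.shape[0]
    prev = None
    history: list[float] = []
    lab = np.zeros(u, dtype=int)
    for _ in range(max_iter):
        dists = batch_dtw(uniq, centroids, squared=squared)
        lab = dists.argmin(axis=1)  # argmin ties -> lowest cluster index
        for c in range(k):  # empty-cluster repair: reseed from the farthest point
            if not np.any(lab == c):
                far = int(np.argmax(dists[np.arange(u), lab]))
                centroids[c] = uniq[far]
                dists[:, c] = batch_dtw(uniq, centroids[c][None, :], squared=squared)[:, 0]
                lab = dists.argmin(axis=1)
        history.append(float((counts * dists[np.arange(u), lab]).sum()))
        if prev is not None and np.array_equal(lab, prev):
            break
        prev = lab.copy()
        for c in range(k):
            m = lab == c
            if centroid == "medoid":
                centroids[c] = uniq[_medoid(np.flatnonzero(m), counts, du)]
            else:
                centroids[c] = _barycenter(uniq[m], counts[m], centroids[c], squared)
    return lab, centroids, history


def kmeans_dtw(
    trajs,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    ids=None,
    objective: str = "squared",
    centroid: str = "dba",
    max_iter: int = 100,
) -> ClusteringResult:
    """Cluster equal-length trajectories into ``k`` groups under DTW.

    Deterministic given ``seed``; the best of ``n_init`` restarts by
    inertia is kept (ties: lowest restart index).  Duplicate trajectories
    are collapsed internally, so ``k`` may not exceed the number of
    *distinct* trajectories.  ``objective`` selects the local cost the
    k-means objective minimizes ("squared", the classical choice, or
    "abs"); the reported silhouette always uses the absolute-cost DTW
    distance.  ``centroid`` is "dba" or "medoid".
    """
    if objective not in ("squared", "abs"):
        raise ValueError("objective must be 'squared' or 'abs'")
    if centroid not in ("dba", "medoid"):
        raise ValueError("centroid must be 'dba' or 'medoid'")
    squared = objective == "squared"
    X, ids_list = _as_matrix(trajs, ids)
    n = X.shape[0]
    if n == 0:
        raise ValueError("no trajectories to cluster")
    if k < 2:
        raise ValueError("k must be at least 2")
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    if k > uniq.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {uniq.shape[0]} distinct trajectories in the input"
        )
    du = batch_dtw(uniq, uniq, squared=squared)
    du = (du + du.T) / 2.0
    np.fill_diagonal(du, 0.0)

    best = None
    for child in np.random.SeedSequence(seed).spawn(n_init):
        rng = np.random.default_rng(child)
        lab_u, centroids, history = _lloyd(uniq, counts, du, k, rng, squared, centroid, max_iter)
        if best is None or history[-1] < best[2][-1]:
            best = (lab_u, centroids, history)
    lab_u, centroids, history = best

    labels = lab_u[inverse]
    if squared:
        du_abs = batch_dtw(uniq, uniq, squared=False)
        du_abs = (du_abs + du_abs.T) / 2.0
        np.fill_diagonal(du_abs, 0.0)
    else:
        du_abs = du
    d_points = du_abs[np.ix_(inverse, inverse)]
    sil = silhouette(DistanceMatrix(ids=ids_list, d=d_points), labels)
    return ClusteringResult(
        k=k,
        ids=ids_list,
        labels=labels,
        centroids=centroids,
        inertia=history[-1],
        silhouette=sil,
        seed=seed,
        n_init=n_init,
        inertia_history=history,
    )


def silhouette(d: DistanceMatrix | np.ndarray, labels) -> float:
    """Mean silhouette of a labeled precomputed distance matrix.

    Per point: ``(b - a) / max(a, b)`` with *a* the mean intra-cluster
    distance (self excluded) and *b* the smallest mean distance to another
    cluster.  Singleton-cluster points contribute 0, as do points with
    ``max(a, b) == 0``.
    """
    D = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    clusters, idx = np.unique(labels, return_inverse=True)
    k = clusters.size
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), idx] = 1.0
    sums = D @ onehot  # (n, k): total distance from each point to each cluster
    sizes = onehot.sum(axis=0)

    scores = np.zeros(n)
    for p in range(n):
        own = idx[p]
        if sizes[own] <= 1:
            continue
        a = sums[p, own] / (sizes[own] - 1)
        other = [sums[p, c] / sizes[c] for c in range(k) if c != own]
        b = min(other)
        denom = max(a, b)
        scores[p] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def select_k(
    trajs,
    k_range=range(3, 8),
    seed: int = 0,
    n_init: int = 10,
    ids=None,
    objective: str = "squared",
    centroid: str = "dba",
) -> ModelSelection:
    """Silhouette-maximizing number of clusters over ``k_range`` (ties: smallest).

    Values of k exceeding the number of distinct trajectories are skipped
    (a k-point partition of fewer distinct points is not defined); at least
    one feasible k is required.
    """
    X, _ = _as_matrix(trajs, ids)
    n_distinct = np.unique(X, axis=0).shape[0]
    ks = sorted(set(int(k) for k in k_range))
    ks = [k for k in ks if k <= n_distinct]
    if not ks:
        raise ValueError("no k in k_range is feasible for the distinct trajectories")
    sil_by_k = {}
    for k in ks:
        sil_by_k[k] = kmeans_dtw(
            trajs, k, seed=seed, n_init=n_init, ids=ids, objective=objective, centroid=centroid
        ).silhouette
    best_k = min(sil_by_k, key=lambda k: (-sil_by_k[k], k))
    return ModelSelection(k_range=tuple(ks), silhouette_by_k=sil_by_k, best_k=best_k)


def name_clusters(result: ClusteringResult) -> dict[int, str]:
    """Map the 4 cluster indices to engagement archetypes by centroid shape.

    Clusters split on week-1 centroid level (high >= 4 days/week), then,
    within each pair, on the week-4 minus week-1 trend: the higher-trend
    member is the stable/rising archetype (PEHH / PELH), the lower-trend
    member the declining one (PEHL / PELL).  A non-2/2 week-1 split cannot
    be named bijectively and raises :class:`ClusterNamingError`.
    """
    if result.k != 4:
        raise ClusterNamingError(f"archetype naming requires k=4, got k={result.k}")
    w1 = result.centroids[:, 0]
    trend = result.centroids[:, -1] - result.centroids[:, 0]
    high = np.flatnonzero(w1 >= HIGH_WEEK1_THRESHOLD)
    low = np.flatnonzero(w1 < HIGH_WEEK1_THRESHOLD)
    if high.size != 2 or low.size != 2:
        raise ClusterNamingError(
            f"week-1 centroid split is {high.size} high / {low.size} low; "
            "cannot assign each archetype exactly once"
        )
    names: dict[int, str] = {}
    hi_sorted = high[np.argsort(trend[high], kind="stable")]
    names[int(hi_sorted[0])] = "PEHL"
    names[int(hi_sorted[1])] = "PEHH"
    lo_sorted = low[np.argsort(trend[low], kind="stable")]
    names[int(lo_sorted[0])] = "PELL"
    names[int(lo_sorted[1])] = "PELH"
    return names
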