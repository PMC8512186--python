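"""Dynamic time warping over engagement trajectories.

DTW here is the minimal cumulative local cost over monotone,
boundary-anchored, contiguous warping paths with the symmetric step
pattern {(1,0), (0,1), (1,1)} and no window constraint.  The default
local cost is the absolute difference, which keeps the distance in
days/week for count-valued series; squared local cost is available via
``squared=True``.  No path-length normalization is applied — all analysis
series share one length, so normalization would only rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _local_cost(a: np.ndarray, b: np.ndarray, squared: bool) -> np.ndarray:
    diff = a[:, None] - b[None, :]
    return diff * diff if squared else np.abs(diff)


def dtw(a, b, squared: bool = False) -> float:
    """DTW distance between two 1-D series (any lengths >= 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires nonempty series")
    cost = _local_cost(a, b, squared)
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
    return float(acc[n, m])


def dtw_path(a, b, squared: bool = False) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance plus one optimal alignment path of (i, j) index pairs.

    Ties during backtracking prefer the diagonal step, then (i-1, j), for
    deterministic alignments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires nonempty series")
    cost = _local_cost(a, b, squared)
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        if acc[i - 1, j - 1] <= acc[i - 1, j] and acc[i - 1, j - 1] <= acc[i, j - 1]:
            i, j = i - 1, j - 1
        elif acc[i - 1, j] <= acc[i, j - 1]:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return float(acc[n, m]), path


def batch_dtw(A: np.ndarray, B: np.ndarray, squared: bool = False) -> np.ndarray:
    """All-pairs DTW between the rows of two equal-length series matrices.

    Vectorizes the dynamic program over the pair axes; intended for the
    short (length <= ~10) weekly series this package works with.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    La, Lb = A.shape[1], B.shape[1]
    if La == 0 or Lb == 0:
        raise ValueError("DTW requires nonempty series")
    diff = A[:, None, :, None] - B[None, :, None, :]
    cost = diff * diff if squared else np.abs(diff)
    acc = np.full((A.shape[0], B.shape[0], La + 1, Lb + 1), np.inf)
    acc[:, :, 0, 0] = 0.0
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            acc[:, :, i, j] = cost[:, :, i - 1, j - 1] + np.minimum(
                acc[:, :, i - 1, j - 1], np.minimum(acc[:, :, i - 1, j], acc[:, :, i, j - 1])
            )
    return acc[:, :, La, Lb]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise DTW distances with patient ids."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def pairwise_dtw(trajs, ids=None, squared: bool = False) -> DistanceMatrix:
    """Full pairwise DTW matrix over equal-length trajectories.

    Accepts a DataFrame (index = patient ids) or a 2-D array.  Duplicate
    trajectories are collapsed before the dynamic program, so the cost
    scales with the number of *distinct* series; each unordered pair is
    computed once and mirrored.
    """
    X, ids = _as_matrix(trajs, ids)
    if X.shape[0] == 0:
        raise ValueError("need at least one trajectory")
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    du = batch_dtw(uniq, uniq, squared=squared)
    du = (du + du.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(du, 0.0)
    d = du[np.ix_(inverse, inverse)]
    return DistanceMatrix(ids=list(ids), d=d)


def _as_matrix(trajs, ids):
    import pandas as pd

    if isinstance(trajs, pd.DataFrame):
        X = trajs.to_numpy(dtype=float)
        ids = list(trajs.index) if ids is None else list(ids)
    else:
        X = np.asarray(trajs, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        ids = list(range(X.shape[0])) if ids is None else list(ids)
    if len(ids) != X.shape[0]:
        raise ValueError("ids length does not match trajectory count")
    if X.ndim != 2:
        raise ValueError("trajectories must be equal-length 1-D series")
    return X, ids
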