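"""Independent oracles used by the test suite.

These deliberately avoid the package's own dynamic programs: the DTW
oracle enumerates every warping path explicitly, and the count-mean
oracle integrates the rounded/clipped normal law in closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def dtw_brute(a, b, squared: bool = False) -> float:
    """Minimal path cost by exhaustive enumeration of all warping paths."""
    a = list(a)
    b = list(b)
    n, m = len(a), len(b)

    def local(i, j):
        d = a[i] - b[j]
        return d * d if squared else abs(d)

    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + local(i, j)
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])


def expected_weekly_count_mean(mu: float, sd: float, floor_one: bool = False) -> float:
    """E[round(clip(N(mu, sd), 0, 7))], optionally floored at 1.

    ``round`` is half-up after clipping, so P(0) = P(X < 0.5) and
    P(7) = P(X >= 6.5); ``floor_one`` maps the 0 outcome to 1 (the
    selection guarantee applied to the first and last horizon weeks).
    """
    if sd == 0:
        k = int(np.floor(np.clip(mu, 0, 7) + 0.5))
        return float(max(k, 1) if floor_one else k)
    probs = {}
    for k in range(8):
        lo = -np.inf if k == 0 else k - 0.5
        hi = np.inf if k == 7 else k + 0.5
        probs[k] = norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)
    if floor_one:
        probs[1] += probs.pop(0)
    return float(sum(k * p for k, p in probs.items()))
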