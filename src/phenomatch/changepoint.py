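"""Pruned Exact Linear Time (PELT) changepoint detection.

Penalised segmentation of a 1-D signal under a Gaussian mean-shift cost:
the cost of a segment is its sum of squared deviations from the segment
mean, and a fixed penalty is paid per changepoint.  PELT minimises

    sum_i cost(segment_i) + penalty * (#changepoints)

exactly; the pruning step (valid because the SSE cost is subadditive, so
the pruning constant K = 0) only discards candidates that can never be
optimal, giving linear expected time when changepoints are frequent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pelt_mean_shift", "segment_cost"]


def segment_cost(values: np.ndarray, start: int, end: int,
                 s1: np.ndarray | None = None,
                 s2: np.ndarray | None = None) -> float:
    """SSE-around-the-mean cost of the half-open segment [start, end)."""
    if s1 is None:
        v = np.asarray(values, dtype=float)
        s1 = np.concatenate([[0.0], np.cumsum(v)])
        s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    m = end - start
    s = s1[end] - s1[start]
    return float(s2[end] - s2[start] - s * s / m)


def pelt_mean_shift(values, penalty: float, min_size: int = 1) -> list[int]:
    """Exact penalised segmentation; returns sorted interior changepoints.

    A changepoint at index c means segments split as [..., c) and [c, ...).
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n == 0:
        return []
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cand = [0]
    for t in range(1, n + 1):
        s = np.array([c for c in cand if t - c >= min_size], dtype=int)
        if len(s) == 0:
            continue
        m = t - s
        seg_sum = s1[t] - s1[s]
        costs = (s2[t] - s2[s]) - seg_sum * seg_sum / m
        totals = f[s] + costs + penalty
        j = int(np.argmin(totals))
        f[t] = totals[j]
        prev[t] = s[j]
        # prune: keep only candidates that could still start an optimal segment
        keep = s[f[s] + costs <= f[t]]
        cand = list(keep) + [t]

    cps = []
    t = n
    while t > 0:
        c = int(prev[t])
        if c > 0:
            cps.append(c)
        t = c
    return sorted(cps)
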