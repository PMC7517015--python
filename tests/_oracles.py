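"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: sample entropy by
explicit O(n^2) template counting in pure Python, DTW by exhaustive
enumeration of every admissible warping path, and AUC by the rank
statistic (Mann-Whitney U).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import mannwhitneyu


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by explicit template-pair counting (pure loops)."""
    x = [float(v) for v in x]
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dm = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > dm:
                    dm = diff
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def dtw_min_cumulative_exhaustive(x, y) -> float:
    """Minimal cumulative cost over ALL admissible warping paths.

    Plain depth-first enumeration (no dynamic programming); feasible only
    for short series (Delannoy-number growth).
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    m, k = len(x), len(y)
    best = [math.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += abs(x[i] - y[j])
        if i == m - 1 and j == k - 1:
            if acc < best[0]:
                best[0] = acc
            return
        if i + 1 < m and j + 1 < k:
            walk(i + 1, j + 1, acc)
        if i + 1 < m:
            walk(i + 1, j, acc)
        if j + 1 < k:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def rank_auc(values, labels) -> float:
    """Exact AUC via the Mann-Whitney U statistic, ties half-weighted.

    Positive (CHF) class scores low, so AUC = P(chf < nsr) + 0.5 P(tie).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    chf = values[labels == "CHF"]
    nsr = values[labels == "NSR"]
    u = mannwhitneyu(nsr, chf, alternative="two-sided").statistic  # pairs with nsr > chf (+ ties/2)
    return float(u) / (len(chf) * len(nsr))
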