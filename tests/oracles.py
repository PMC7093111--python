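"""Independent oracles used to cross-check the implementation.

Deliberately written along different routes than the package code: exact
integer arithmetic for 2 x c exact tests, a vectorized permutation sampler
for general tables, and a literal threshold scan for the regulation rule.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np


def regulation_scan(profile: dict[int, float], intact: float, fold: float) -> str:
    """Literal per-timepoint scan of the fold rule (RNA-seq)."""
    up = down = False
    for t, v in profile.items():
        if t == 0:
            continue
        if v >= fold * intact:
            up = True
        if v <= intact / fold:
            down = True
    return {(True, True): "mixed", (True, False): "up",
            (False, True): "down", (False, False): "none"}[(up, down)]


def fisher_2xc_exact(table: np.ndarray) -> float:
    """Exact two-sided p for a 2 x c table in pure integer arithmetic.

    Conditional on margins, the first row (x_1..x_c) has probability
    prod_j C(c_j, x_j) / C(N, r_1); the p-value sums the weights of all
    first rows no heavier than the observed one. Integer weights make the
    tie comparison exact.
    """
    table = np.asarray(table)
    assert table.shape[0] == 2
    cols = table.sum(axis=0)
    r1 = int(table[0].sum())
    n_total = int(table.sum())

    def weights(j: int, rem: int):
        if j == len(cols) - 1:
            if rem <= cols[j]:
                yield comb(int(cols[j]), rem), (rem,)
            return
        for x in range(min(rem, int(cols[j])) + 1):
            for w, rest in weights(j + 1, rem - x):
                yield comb(int(cols[j]), x) * w, (x,) + rest

    all_w = [w for w, _ in weights(0, r1)]
    obs_w = 1
    for j, x in enumerate(table[0]):
        obs_w *= comb(int(cols[j]), int(x))
    num = sum(w for w in all_w if w <= obs_w)
    return num / comb(n_total, r1)


def fisher_mc_permutation(
    table: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo permutation estimate of the exact two-sided p.

    Fixes the row assignment of N items, permutes the column labels, and
    counts resampled tables no more probable than the observed one.
    Returns (p_hat, standard_error).
    """
    table = np.asarray(table)
    r, c = table.shape
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n_total = int(table.sum())
    lg = np.array([math.lgamma(k + 1) for k in range(n_total + 1)])

    def log_prob(counts: np.ndarray) -> np.ndarray:
        # margins fixed -> only the cell factorials vary
        return -lg[counts].sum(axis=(-2, -1))

    obs = log_prob(table[None])[0]

    col_labels = np.repeat(np.arange(c), cols)
    row_starts = np.concatenate([[0], np.cumsum(rows)])
    keys = rng.random((n_resamples, n_total))
    perm = col_labels[np.argsort(keys, axis=1)]
    counts = np.empty((n_resamples, r, c), dtype=np.int64)
    for i in range(r):
        seg = perm[:, row_starts[i]:row_starts[i + 1]]
        for j in range(c):
            counts[:, i, j] = (seg == j).sum(axis=1)
    lp = log_prob(counts)
    hits = lp <= obs + 1e-9
    p_hat = hits.mean()
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_resamples)
    return float(p_hat), se
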