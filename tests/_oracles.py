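"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def floyd_warshall_distances(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by the Floyd-Warshall recurrence."""
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def global_efficiency_oracle(adjacency: np.ndarray) -> float:
    dist = floyd_warshall_distances(adjacency)
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bh_stepup_oracle(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: find the largest k with
    p_(k) <= k q / m and reject all hypotheses with p <= p_(k)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    if k_max:
        reject[order[:k_max]] = True
    return reject


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing the average of their positions."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank both vectors (average ranks for ties), then Pearson."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def partial_f_oracle(y, x_full, x_reduced) -> tuple[float, float]:
    """Partial F via explicit normal equations: F and its p-value."""
    from scipy import stats

    def sse(x):
        xtx = x.T @ x
        beta = np.linalg.solve(xtx, x.T @ y)
        r = y - x @ beta
        return float(r @ r)

    sse_f, sse_r = sse(x_full), sse(x_reduced)
    df_num = x_full.shape[1] - x_reduced.shape[1]
    df_den = len(y) - x_full.shape[1]
    f = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    return f, float(stats.f.sf(f, df_num, df_den))
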