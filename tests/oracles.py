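"""Independent, deliberately naive reference implementations.

Everything here is written from the definitions with plain loops and
explicit projection matrices, never calling the package's own fast paths,
so the test suite can compare the two routes.
"""

from __future__ import annotations

import numpy as np


def zscore(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=ddof)


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    return d


def fad_naive(d: np.ndarray, members) -> float:
    members = list(members)
    total = 0.0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            total += d[members[a], members[b]]
    return total


def rao_q_naive(d: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    n = len(w)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += d[i, j] * w[i] * w[j]
    return total


def fdis_naive(X: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    c = np.zeros(X.shape[1])
    for i in range(len(w)):
        c += w[i] * X[i]
    total = 0.0
    for i in range(len(w)):
        total += w[i] * np.sqrt(np.sum((X[i] - c) ** 2))
    return total


def upgma_naive(d: np.ndarray):
    """Textbook UPGMA by repeated merging of the closest cluster pair.

    Returns (merges, heights): merges is a list of (cluster_a, cluster_b,
    cophenetic_distance, new_size) exactly mirroring a linkage matrix row;
    node heights (half the merge distance) and branch lengths follow.
    """
    n = d.shape[0]
    active = {i: [i] for i in range(n)}           # node id -> tip list
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), dd = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        tips = active[a] + active[b]
        merges.append((a, b, dd, len(tips)))
        for c in list(active):
            if c in (a, b):
                continue
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            new = (len(active[a]) * dist[key_a] + len(active[b]) * dist[key_b]) \
                / (len(active[a]) + len(active[b]))
            dist[(min(next_id, c), max(next_id, c))] = new
        for c in list(active):
            dist.pop((min(a, c), max(a, c)), None)
            dist.pop((min(b, c), max(b, c)), None)
        del active[a], active[b]
        active[next_id] = tips
        next_id += 1
    return merges


def upgma_total_branch_length(merges, n: int) -> float:
    heights = {i: 0.0 for i in range(n)}
    total = 0.0
    for k, (a, b, dd, _) in enumerate(merges):
        h = dd / 2.0
        heights[n + k] = h
        total += (h - heights[a]) + (h - heights[b])
    return total


def subtree_length_naive(merges, n: int, present) -> float:
    """Branch length of the minimal subtree spanning the present tips,
    excluding any path above their last common merge."""
    heights = {i: 0.0 for i in range(n)}
    children = {}
    tipsets = {i: {i} for i in range(n)}
    for k, (a, b, dd, _) in enumerate(merges):
        node = n + k
        heights[node] = dd / 2.0
        children[node] = (a, b)
        tipsets[node] = tipsets[a] | tipsets[b]
    present = set(present)
    total = 0.0
    for node, (a, b) in children.items():
        for child in (a, b):
            below = tipsets[child] & present
            if below and below != present:
                total += heights[node] - heights[child]
    return total


def rm_naive(X: np.ndarray, subset) -> float:
    """Matrix correlation between X and its projection onto the span of
    the subset columns, via the explicit projection matrix."""
    Xk = X[:, list(subset)]
    P = Xk @ np.linalg.pinv(Xk.T @ Xk) @ Xk.T
    num = np.trace(X.T @ P @ X)
    den = np.sqrt(np.trace(X.T @ X) * np.trace((P @ X).T @ (P @ X)))
    return float(num / den)


def rv_naive(X: np.ndarray, subset) -> float:
    """Configuration similarity corr(XXᵗ, P XXᵗ P) from explicit matrices."""
    Xk = X[:, list(subset)]
    P = Xk @ np.linalg.pinv(Xk.T @ Xk) @ Xk.T
    A = X @ X.T
    B = P @ A @ P
    return float(np.trace(A @ B) / np.sqrt(np.trace(A @ A) * np.trace(B @ B)))


def gcd_naive(X: np.ndarray, subset, pc_set) -> float:
    """tr(P_k P_g)/sqrt(kg) with both projections built explicitly."""
    Xk = X[:, list(subset)]
    Pk = Xk @ np.linalg.pinv(Xk.T @ Xk) @ Xk.T
    n = X.shape[0]
    S = X.T @ X / n
    ev, vec = np.linalg.eigh(S)
    order = np.argsort(ev)[::-1]
    V = vec[:, order][:, list(pc_set)]
    Y = X @ V  # PC score columns
    Pg = Y @ np.linalg.pinv(Y.T @ Y) @ Y.T
    return float(np.trace(Pk @ Pg) / np.sqrt(len(subset) * len(pc_set)))


def ols_cod_naive(x: np.ndarray, y: np.ndarray):
    """Closed-form simple regression: r², slope and the t-test p of the
    slope."""
    from scipy import stats

    n = len(x)
    r = np.corrcoef(x, y)[0, 1]
    slope = r * y.std(ddof=1) / x.std(ddof=1)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r ** 2, slope, p
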