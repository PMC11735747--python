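"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles — textbook formulas,
exhaustive enumeration over triples or simple paths, the literal
step-up definition of Benjamini-Hochberg, projection-matrix least
squares — so that agreement with the package is a genuine two-route
check, not a reimplementation of the same code path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson(x, y) -> float:
    """Textbook covariance-over-sds Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm * xm).sum() * (ym * ym).sum()))


def bf_strength(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n) if j != i) for i in range(n)])


def bf_clustering_binary(w: np.ndarray) -> np.ndarray:
    """Triangle enumeration over all node triples on the binarised graph."""
    n = w.shape[0]
    a = w > 0
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        tri = sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u, v])
        out[i] = 2.0 * tri / (d * (d - 1))
    return out


def bf_clustering_weighted(w: np.ndarray) -> np.ndarray:
    """Geometric-mean (Onnela) weighted clustering via triple enumeration."""
    n = w.shape[0]
    a = w > 0
    wmax = w.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        acc = 0.0
        for u, v in itertools.combinations(nbrs, 2):
            if a[u, v]:
                acc += ((w[i, u] / wmax) * (w[i, v] / wmax) * (w[u, v] / wmax)) ** (1 / 3)
        out[i] = 2.0 * acc / (d * (d - 1))
    return out


def bf_shortest_paths(w: np.ndarray, mapping: str = "inverse") -> np.ndarray:
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    n = w.shape[0]
    if mapping == "inverse":
        def length(u, v):
            return 1.0 / w[u, v]
    else:
        def length(u, v):
            return -math.log(w[u, v])

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            best = np.inf
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (i, *mid, j)
                    if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                        best = min(best, sum(length(a, b) for a, b in zip(path, path[1:])))
            dist[i, j] = best
    return dist


def bf_characteristic_path_length(dist: np.ndarray) -> tuple[float, float]:
    n = dist.shape[0]
    finite = [dist[i, j] for i in range(n) for j in range(n)
              if i != j and math.isfinite(dist[i, j])]
    if not finite:
        raise ValueError("no finite pair")
    return sum(finite) / len(finite), len(finite) / (n * (n - 1))


def bf_global_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_local_efficiency(w: np.ndarray, mapping: str = "inverse") -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(bf_shortest_paths(sub, mapping))
    return out


def bh_stepup(pvalues, q: float) -> np.ndarray:
    """The literal Benjamini-Hochberg definition: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def ancova_f(y, x_full, x_reduced, df_num: int) -> float:
    """Group F from residual sums of squares via explicit projection matrices."""
    y = np.asarray(y, float)

    def rss(x):
        x = np.asarray(x, float)
        h = x @ np.linalg.inv(x.T @ x) @ x.T
        r = y - h @ y
        return float(r @ r)

    rss_f, rss_r = rss(x_full), rss(x_reduced)
    n, p = np.asarray(x_full).shape
    return ((rss_r - rss_f) / df_num) / (rss_f / (n - p))


def random_graph(rng: np.random.Generator, n_max: int = 7, p_edge: float = 0.5
                 ) -> np.ndarray:
    """Random symmetric weighted graph with weights in (0.1, 1]."""
    n = int(rng.integers(3, n_max + 1))
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w
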