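"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive path enumeration,
direct triple loops, textbook normal equations — and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_degree(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(1 for j in range(n) if j != i and w[i, j] > 0) for i in range(n)])


def brute_strength(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n) if j != i) for i in range(n)])


def brute_onnela_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    what = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    """Yield every simple path s->t as a node list (DFS)."""
    n = w.shape[0]
    neighbors = [[j for j in range(n) if w[i, j] > 0] for i in range(n)]
    path = [s]
    on_path = [False] * n
    on_path[s] = True

    def dfs(u):
        if u == t:
            yield list(path)
            return
        for v in neighbors[u]:
            if not on_path[v]:
                on_path[v] = True
                path.append(v)
                yield from dfs(v)
                path.pop()
                on_path[v] = False

    yield from dfs(s)


def _path_cost(w: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances by exhaustive path enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            best = np.inf
            for path in _all_simple_paths(w, s, t):
                best = min(best, _path_cost(w, path))
            d[s, t] = d[t, s] = best
    return d


def brute_betweenness(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unnormalized betweenness: enumerate every shortest path of every
    unordered pair and share the count fractionally among ties."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(_all_simple_paths(w, s, t))
            if not paths:
                continue
            costs = [_path_cost(w, p) for p in paths]
            best = min(costs)
            shortest = [p for p, c in zip(paths, costs) if c <= best + tol]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def brute_nodal_path_length(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        out[i] = float(np.mean(vals)) if vals else 0.0
    return out


def brute_global(w: np.ndarray) -> dict[str, float]:
    d = brute_distances(w)
    n = w.shape[0]
    finite, inv = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                finite.append(d[i, j])
                inv.append(1.0 / d[i, j])
            else:
                inv.append(0.0)
    return {
        "mean_degree": float(np.mean(brute_degree(w))),
        "mean_strength": float(np.mean(brute_strength(w))),
        "clustering": float(np.mean(brute_onnela_clustering(w))),
        "path_length": float(np.mean(finite)) if finite else float("nan"),
        "global_efficiency": float(np.mean(inv)),
    }


def brute_ols(x: np.ndarray, y: np.ndarray):
    """Textbook normal-equations OLS: (beta, se, t, two-sided p, rss)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - k)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return beta, se, t, p, rss


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, spelled out."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def random_weighted_graph(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Random symmetric weighted adjacency matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < density
    vals = np.where(present, rng.uniform(0.1, 2.0, len(iu[0])), 0.0)
    w[iu] = vals
    return w + w.T
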