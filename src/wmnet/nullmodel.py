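"""Degree-preserving random-graph null models and normalized measures.

Normalized global measures scale the raw clustering coefficient,
characteristic path length, and global efficiency against their mean
values over an ensemble (default 100) of matched random graphs that
preserve the number of nodes, the number of edges, and the exact degree
sequence, generated by Maslov-Sneppen double-edge swaps. Weights travel
with the rewired edges, so the weight multiset is preserved as well:

    gamma  = C / <C_rand>
    lambda = L / <L_rand>
    normalized E_glob = E_glob / <E_glob,rand>
    sigma  = gamma / lambda
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .measures import (
    GlobalMeasures,
    _path_summaries,
    local_clustering,
    shortest_path_distances,
)
from .network import WeightedNetwork

__all__ = [
    "NullEnsembleSpec",
    "rewire_degree_preserving",
    "normalize_globals",
    "subject_seed",
]

_MAX_TRIES_PER_SWAP = 100


@dataclass(frozen=True)
class NullEnsembleSpec:
    """Configuration of the random-graph ensemble.

    ``n_graphs`` matched random graphs, each produced by
    ``swaps_per_edge`` x (edge count) double-edge swap attempts.
    """

    n_graphs: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_graphs < 1 or self.swaps_per_edge < 1:
            raise ValueError("n_graphs and swaps_per_edge must be >= 1")


@njit(cache=True)
def _rewire_kernel(w, edges, n_swaps, max_tries, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    m = edges.shape[0]
    skipped = 0
    for _ in range(n_swaps):
        done = False
        for _ in range(max_tries):
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            a = edges[e1, 0]
            b = edges[e1, 1]
            c = edges[e2, 0]
            d = edges[e2, 1]
            if np.random.randint(2) == 1:
                tmp = c
                c = d
                d = tmp
            if a == c or a == d or b == c or b == d:
                continue
            # proposed swap: (a-b, c-d) -> (a-d, c-b)
            if w[a, d] != 0.0 or w[c, b] != 0.0:
                continue
            w1 = w[a, b]
            w2 = w[c, d]
            w[a, b] = 0.0
            w[b, a] = 0.0
            w[c, d] = 0.0
            w[d, c] = 0.0
            w[a, d] = w1
            w[d, a] = w1
            w[c, b] = w2
            w[b, c] = w2
            edges[e1, 0] = a
            edges[e1, 1] = d
            edges[e2, 0] = c
            edges[e2, 1] = b
            done = True
            break
        if not done:
            skipped += 1
    return skipped


def rewire_degree_preserving(
    net: WeightedNetwork | np.ndarray,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, int]:
    """Randomize topology by double-edge swaps, preserving degrees.

    Swap attempts that would create a self-loop or a multi-edge are
    rejected; a swap that finds no legal move within 100 proposals is
    skipped and counted. Returns ``(rewired weight matrix, n_skipped)``.
    With fewer than 2 edges the input is returned unchanged with a
    warning.
    """
    w = (net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, float)).copy()
    rng = np.random.default_rng(rng)
    ii, jj = np.nonzero(np.triu(w, 1))
    m = len(ii)
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire", stacklevel=2)
        return w, 0
    edges = np.stack([ii, jj], axis=1).astype(np.int64)
    seed = int(rng.integers(0, 2**31 - 1))
    skipped = int(
        _rewire_kernel(w, edges, swaps_per_edge * m, _MAX_TRIES_PER_SWAP, seed)
    )
    return w, skipped


def _raw_cle(w: np.ndarray) -> tuple[float, float, float]:
    """(mean clustering, characteristic path length, global efficiency)."""
    c = float(local_clustering(w).mean())
    cpl, eglob = _path_summaries(shortest_path_distances(w))
    return c, cpl, eglob


def normalize_globals(
    net: WeightedNetwork | np.ndarray,
    raw: GlobalMeasures,
    spec: NullEnsembleSpec = NullEnsembleSpec(),
) -> GlobalMeasures:
    """Fill gamma, lambda, normalized E_glob and sigma on ``raw``.

    The ensemble is reproducible from ``spec.seed``. If an ensemble mean
    is 0 (or the corresponding raw value is undefined), the normalized
    value is left as NaN with a warning.
    """
    w = net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, float)
    root = np.random.SeedSequence(spec.seed)
    c_rand = np.empty(spec.n_graphs)
    l_rand = np.empty(spec.n_graphs)
    e_rand = np.empty(spec.n_graphs)
    total_skipped = 0
    for g, child in enumerate(root.spawn(spec.n_graphs)):
        rewired, skipped = rewire_degree_preserving(
            w, spec.swaps_per_edge, np.random.default_rng(child)
        )
        total_skipped += skipped
        c_rand[g], l_rand[g], e_rand[g] = _raw_cle(rewired)

    def _ratio(value: float, ensemble: np.ndarray, name: str) -> float:
        mean = float(np.nanmean(ensemble))
        if not np.isfinite(mean) or mean == 0.0 or not np.isfinite(value):
            warnings.warn(f"cannot normalize {name}: degenerate ensemble mean", stacklevel=3)
            return float("nan")
        return value / mean

    gamma = _ratio(raw.clustering, c_rand, "clustering")
    lam = _ratio(raw.path_length, l_rand, "path length")
    e_norm = _ratio(raw.global_efficiency, e_rand, "global efficiency")
    out = GlobalMeasures(
        mean_degree=raw.mean_degree,
        mean_strength=raw.mean_strength,
        clustering=raw.clustering,
        path_length=raw.path_length,
        global_efficiency=raw.global_efficiency,
        gamma=gamma,
        lambda_=lam,
        normalized_global_efficiency=e_norm,
        sigma=gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan"),
        null_ensemble={
            "n_graphs": spec.n_graphs,
            "clustering_mean": float(np.nanmean(c_rand)),
            "clustering_sd": float(np.nanstd(c_rand)),
            "path_length_mean": float(np.nanmean(l_rand)),
            "path_length_sd": float(np.nanstd(l_rand)),
            "global_efficiency_mean": float(np.nanmean(e_rand)),
            "global_efficiency_sd": float(np.nanstd(e_rand)),
            "skipped_swaps": total_skipped,
        },
    )
    return out


def subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject seed derived from a global seed and subject id."""
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(subject_id.encode())]
        ).generate_state(1)[0]
        % (2**31 - 1)
    )
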