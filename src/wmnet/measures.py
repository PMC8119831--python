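"""Local and global graph measures on weighted undirected networks.

Five local measures per node — degree, strength, Onnela weighted
clustering, nodal shortest path length, and (unnormalized) betweenness
centrality — and the raw global measures: mean degree, mean strength,
mean clustering C, characteristic path length L, and global efficiency
E_glob. Normalized global measures (gamma, lambda, normalized E_glob,
small-worldness sigma) are filled in by :mod:`wmnet.nullmodel`.

Conventions
-----------
* Degree is computed on the binarized network; strength on the weights.
* Edge length for shortest paths is the inverse weight, d_ij = 1/w_ij.
* Clustering uses the Onnela geometric-mean form on weights rescaled by
  the network-wide maximum, so it is invariant to a global weight scale.
* L and the nodal path length average over *reachable* pairs only;
  unreachable pairs contribute 0 to E_glob.
* Betweenness shares equal-length shortest paths fractionally (Brandes)
  and counts each unordered endpoint pair once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import WeightedNetwork, binarize

__all__ = [
    "LocalMeasures",
    "GlobalMeasures",
    "node_degree",
    "node_strength",
    "local_clustering",
    "shortest_path_distances",
    "nodal_path_length",
    "betweenness",
    "global_measures",
    "measure_network",
    "LOCAL_MEASURE_NAMES",
    "GLOBAL_MEASURE_NAMES",
]

LOCAL_MEASURE_NAMES = ("degree", "strength", "clustering", "path_length", "betweenness")
GLOBAL_MEASURE_NAMES = (
    "mean_degree",
    "mean_strength",
    "clustering",
    "path_length",
    "global_efficiency",
    "gamma",
    "lambda",
    "normalized_global_efficiency",
    "sigma",
)


def _weights_of(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    return net.weights if isinstance(net, WeightedNetwork) else np.asarray(net, float)


@dataclass
class LocalMeasures:
    """Per-node measure vectors for one network."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    betweenness: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in LOCAL_MEASURE_NAMES}


@dataclass
class GlobalMeasures:
    """Raw global scalars plus normalized fields (None until normalized).

    ``sigma`` is defined as gamma / lambda exactly.
    """

    mean_degree: float
    mean_strength: float
    clustering: float
    path_length: float
    global_efficiency: float
    gamma: float | None = None
    lambda_: float | None = None
    normalized_global_efficiency: float | None = None
    sigma: float | None = None
    null_ensemble: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "mean_degree": self.mean_degree,
            "mean_strength": self.mean_strength,
            "clustering": self.clustering,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "normalized_global_efficiency": self.normalized_global_efficiency,
            "sigma": self.sigma,
        }


def node_degree(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Number of edges incident to each node."""
    return binarize(_weights_of(net)).sum(axis=1).astype(np.int64)


def node_strength(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Sum of incident edge weights per node."""
    return _weights_of(net).sum(axis=1)


def local_clustering(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With w_hat = w / max(w), C_i = sum_{jh} (w_hat_ij w_hat_ih w_hat_jh)^{1/3}
    / (k_i (k_i - 1)); nodes with degree < 2 get 0.
    """
    w = _weights_of(net)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    w_hat_cbrt = np.cbrt(w / wmax)
    cycles = np.diagonal(w_hat_cbrt @ w_hat_cbrt @ w_hat_cbrt)
    k = binarize(w).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cycles / denom, 0.0)
    return c


def shortest_path_distances(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distance matrix with edge lengths 1/w.

    Unreachable pairs are infinite; the diagonal is 0.
    """
    w = _weights_of(net)
    rows, cols = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[rows, cols], (rows, cols)), shape=w.shape)
    return shortest_path(lengths, method="D", directed=False)


def nodal_path_length(distances: np.ndarray) -> np.ndarray:
    """Mean finite shortest-path distance from each node to the others.

    A node reaching no other node gets 0, with a warning.
    """
    n = distances.shape[0]
    d = distances.copy()
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    counts = finite.sum(axis=1)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} isolated node(s): nodal path length set to 0",
            stacklevel=2,
        )
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out if n else out


def _to_length_graph(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    return g


def betweenness(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness centrality (Brandes, lengths 1/w).

    Each unordered endpoint pair is counted once; shortest-path ties are
    shared fractionally.
    """
    w = _weights_of(net)
    bc = nx.betweenness_centrality(_to_length_graph(w), weight="length", normalized=False)
    return np.array([bc[i] for i in range(w.shape[0])])


def global_measures(
    net: WeightedNetwork | np.ndarray,
    distances: np.ndarray | None = None,
    locals_: LocalMeasures | None = None,
) -> GlobalMeasures:
    """Raw global measures; normalized fields are left unset.

    For an edgeless network L is undefined: it is reported as NaN with a
    warning and E_glob is 0.
    """
    w = _weights_of(net)
    if distances is None:
        distances = shortest_path_distances(w)
    if locals_ is not None:
        k = locals_.degree
        s = locals_.strength
        c = locals_.clustering
    else:
        k = node_degree(w)
        s = node_strength(w)
        c = local_clustering(w)
    cpl, eglob = _path_summaries(distances)
    if not np.isfinite(cpl):
        warnings.warn("network has no connected pairs: L undefined (NaN)", stacklevel=2)
    return GlobalMeasures(
        mean_degree=float(np.mean(k)),
        mean_strength=float(np.mean(s)),
        clustering=float(np.mean(c)),
        path_length=cpl,
        global_efficiency=eglob,
    )


def _path_summaries(distances: np.ndarray) -> tuple[float, float]:
    """(characteristic path length over finite pairs, global efficiency)."""
    n = distances.shape[0]
    if n < 2:
        return float("nan"), 0.0
    off = ~np.eye(n, dtype=bool)
    d = distances[off]
    finite = np.isfinite(d)
    cpl = float(d[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / d, 0.0)
    eglob = float(inv.mean())
    return cpl, eglob


def measure_network(net: WeightedNetwork | np.ndarray) -> tuple[LocalMeasures, GlobalMeasures]:
    """Compute all five local measures and the raw global measures."""
    w = _weights_of(net)
    distances = shortest_path_distances(w)
    loc = LocalMeasures(
        degree=node_degree(w),
        strength=node_strength(w),
        clustering=local_clustering(w),
        path_length=nodal_path_length(distances),
        betweenness=betweenness(w),
    )
    glob = global_measures(w, distances, loc)
    return loc, glob
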