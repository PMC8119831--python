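"""Weighted structural network construction from tractography tallies.

A subject's raw data are a symmetric streamline-count matrix, a matrix
of mean FA values along the streamlines connecting each node pair, the
parcel volumes, and the intracranial volume. An edge is kept when at
least ``min_streamlines`` streamlines connect the pair end-to-end, and
its weight is

    w_ij = count_ij * meanFA_ij / ((vol_i + vol_j) / 2)

i.e. the streamline count times the mean FA (equivalently, the sum of
per-streamline mean FA), divided by the average volume of the two
parcels to discount parcel size. The alternative reading that weights
by mean FA alone (without the count factor) is available through
``weight_scheme="fa"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .parcellation import Parcellation, default_parcellation

__all__ = [
    "SubjectRaw",
    "WeightedNetwork",
    "build_network",
    "binarize",
    "InvalidInputError",
]

DEFAULT_MIN_STREAMLINES = 3
_SYMMETRY_TOL = 1e-8


class InvalidInputError(ValueError):
    """Raised when raw subject matrices violate their contracts."""


def _check_square_symmetric(a: np.ndarray, name: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=_SYMMETRY_TOL, rtol=0.0):
        i, j = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
        raise InvalidInputError(
            f"{name} is not symmetric: [{i},{j}]={a[i, j]!r} vs [{j},{i}]={a[j, i]!r}"
        )


@dataclass
class SubjectRaw:
    """Raw per-subject connectome inputs.

    ``counts`` and ``mean_fa`` are symmetric with zero diagonal;
    ``mean_fa`` is zero wherever ``counts`` is zero; ``volumes`` are the
    parcel volumes in mm^3 and ``icv`` the intracranial volume in mm^3.
    """

    counts: np.ndarray
    mean_fa: np.ndarray
    volumes: np.ndarray
    icv: float
    subject_id: str = ""

    def validate(self, parcellation: Parcellation | None = None) -> None:
        _check_square_symmetric(self.counts, "counts")
        _check_square_symmetric(self.mean_fa, "mean_fa")
        n = self.counts.shape[0]
        if self.mean_fa.shape[0] != n or self.volumes.shape != (n,):
            raise InvalidInputError("counts / mean_fa / volumes dimensions disagree")
        if parcellation is not None and parcellation.n_nodes != n:
            raise InvalidInputError(
                f"matrix size {n} does not match parcellation ({parcellation.n_nodes})"
            )
        if np.any(np.diag(self.counts) != 0) or np.any(np.diag(self.mean_fa) != 0):
            raise InvalidInputError("diagonals must be zero")
        if np.any(self.counts < 0):
            raise InvalidInputError("streamline counts must be nonnegative")
        if np.any((self.mean_fa < 0) | (self.mean_fa > 1)):
            raise InvalidInputError("mean FA must lie in [0, 1]")
        if np.any(self.mean_fa[self.counts == 0] != 0):
            raise InvalidInputError("mean FA must be 0 where the count is 0")
        if np.any(self.volumes <= 0):
            raise InvalidInputError("parcel volumes must be positive")
        if self.icv <= 0:
            raise InvalidInputError("ICV must be positive")


@dataclass
class WeightedNetwork:
    """A symmetric nonnegative edge-weight matrix over a parcellation."""

    weights: np.ndarray
    parcellation: Parcellation

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def validate(self) -> None:
        _check_square_symmetric(self.weights, "weights")
        if self.weights.shape[0] != self.parcellation.n_nodes:
            raise InvalidInputError("weights do not match parcellation size")
        if np.any(np.diag(self.weights) != 0):
            raise InvalidInputError("diagonal must be zero")
        if np.any(self.weights < 0):
            raise InvalidInputError("weights must be nonnegative")


def build_network(
    raw: SubjectRaw,
    min_streamlines: int = DEFAULT_MIN_STREAMLINES,
    parcellation: Parcellation | None = None,
    weight_scheme: Literal["count_fa", "fa"] = "count_fa",
) -> WeightedNetwork:
    """Build the subject's weighted, undirected structural network.

    Node pairs connected by fewer than ``min_streamlines`` streamlines
    are treated as unconnected (weight 0). Retained edges are weighted
    by count x mean FA (default) or mean FA alone, divided by the
    average volume of the two parcels.
    """
    if min_streamlines < 1:
        raise InvalidInputError("min_streamlines must be >= 1")
    if parcellation is None:
        n = raw.counts.shape[0]
        parcellation = (
            default_parcellation()
            if n == default_parcellation().n_nodes
            else Parcellation(
                tuple(f"node{i:03d}_{'L' if i % 2 == 0 else 'R'}" for i in range(n)),
                tuple("L" if i % 2 == 0 else "R" for i in range(n)),
            )
        )
    raw.validate(parcellation)

    keep = raw.counts >= min_streamlines
    if weight_scheme == "count_fa":
        numer = raw.counts * raw.mean_fa
    elif weight_scheme == "fa":
        numer = raw.mean_fa
    else:
        raise InvalidInputError(f"unknown weight_scheme {weight_scheme!r}")
    avg_vol = (raw.volumes[:, None] + raw.volumes[None, :]) / 2.0
    weights = np.where(keep, numer / avg_vol, 0.0)
    np.fill_diagonal(weights, 0.0)
    # exact symmetry despite floating-point division
    weights = np.triu(weights, 1)
    weights = weights + weights.T
    return WeightedNetwork(weights=weights, parcellation=parcellation)


def binarize(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """0/1 adjacency matrix: 1 where weight > 0."""
    w = net.weights if isinstance(net, WeightedNetwork) else np.asarray(net)
    adj = (w > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj
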