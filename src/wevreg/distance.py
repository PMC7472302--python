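"""Weighted Minkowski distances and exact k-nearest-neighbour search.

The evidential regressor measures similarity between observations with a
per-feature weighted Minkowski distance

    d_w(x, x') = ( sum_k |w_k (x_k - x'_k)|^p )^(1/p),      w_k >= 0,

so that the learned weight vector ``w`` doubles as a feature-importance
profile: a weight of zero erases a feature from the metric entirely.
Because the weights are nonnegative, d_w equals the unweighted Minkowski
distance between the elementwise-transformed points ``w * x`` and
``w * x'``; the search below exploits that transform and is always exact
(exhaustive), which is the correctness surface of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceParams",
    "NeighborSet",
    "weighted_minkowski",
    "knn_search",
    "as_weight_vector",
]


def as_weight_vector(w: ArrayLike, q: int | None = None) -> NDArray[np.float64]:
    """Validate a per-feature weight vector: finite, nonnegative, length q.

    Negative entries are clipped to 0 (the transform trick requires w >= 0);
    non-finite entries are an error.
    """
    w = np.asarray(w, dtype=float).ravel()
    if not np.all(np.isfinite(w)):
        raise ValueError("weight vector contains non-finite entries")
    if q is not None and w.size != q:
        raise ValueError(f"weight vector has length {w.size}, expected {q}")
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class DistanceParams:
    """Minkowski exponent ``p`` in [1, 2] and RBF discount radius ``gamma`` > 0."""

    p: float = 2.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.p <= 2.0):
            raise ValueError(f"p must lie in [1, 2], got {self.p}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass(frozen=True)
class NeighborSet:
    """k nearest training rows for one query, distances sorted ascending."""

    indices: NDArray[np.intp]
    distances: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have equal length")

    def __len__(self) -> int:
        return self.indices.size


def _check_pair(xi: ArrayLike, xj: ArrayLike, w: ArrayLike) -> tuple[NDArray, NDArray, NDArray]:
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    wv = as_weight_vector(w)
    if not (xi.size == xj.size == wv.size):
        raise ValueError(
            f"dimension mismatch: xi has {xi.size}, xj has {xj.size}, w has {wv.size}"
        )
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise ValueError("input vectors contain non-finite entries")
    return xi, xj, wv


def weighted_minkowski(xi: ArrayLike, xj: ArrayLike, w: ArrayLike, p: float = 2.0) -> float:
    """Weighted Minkowski distance ``(sum_k |w_k (x_ik - x_jk)|^p)^(1/p)``.

    Reduces to the ordinary Minkowski distance when ``w`` is all ones.
    Symmetric, nonnegative, and positively homogeneous in ``w``.
    """
    if not (1.0 <= p <= 2.0):
        raise ValueError(f"p must lie in [1, 2], got {p}")
    xi, xj, wv = _check_pair(xi, xj, w)
    return float(np.sum(np.abs(wv * (xi - xj)) ** p) ** (1.0 / p))


def knn_search(
    X: ArrayLike,
    x: ArrayLike,
    w: ArrayLike,
    k: int,
    p: float = 2.0,
    exclude: int | None = None,
) -> NeighborSet:
    """Exact k-NN of ``x`` among the rows of ``X`` under the weighted metric.

    Ties in distance are broken by ascending row index (deterministic).
    If ``k`` exceeds the number of available rows, all rows are returned
    with a logged warning. ``exclude`` drops one row id (leave-one-out).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    wv = as_weight_vector(w, X.shape[1])
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size != X.shape[1]:
        raise ValueError(f"query has {x.size} features, training rows have {X.shape[1]}")

    # transform trick: weighted Minkowski == plain Minkowski in (w * x) space
    d = np.sum(np.abs(X * wv - x * wv) ** p, axis=1) ** (1.0 / p)
    if exclude is not None:
        d = d.copy()
        d[exclude] = np.inf
    available = d.size - (1 if exclude is not None else 0)
    if available < 1:
        raise ValueError("no training rows available after exclusion")
    if k > available:
        logger.warning("k=%d exceeds available rows (%d); returning all rows", k, available)
        k = available
    order = np.argsort(d, kind="stable")[:k]  # stable sort => index tie-break
    return NeighborSet(indices=order, distances=d[order])
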