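"""Evidential (Dempster–Shafer) mass assignment and Pignistic prediction.

Each training example ``e_i = (x_i, y_i)`` is a piece of evidence about the
target of a query ``x``. Its strength is a discounted similarity

    phi_i = phi(d_w(x, x_i)),     phi(d) = exp(-d^2 / gamma),

and Dempster's rule over the k nearest neighbours N(x) yields the masses

    m_i = (1/K) phi_i * prod_{h != i} (1 - phi_h)            (i in N(x))
    m*  = (1/K) prod_i (1 - phi_i)                           (domain mass)

with K the usual normalization so that sum_i m_i + m* = 1. The domain mass
m* is the model's ignorance: it pushes the prediction toward the midpoint
of the observed target interval [y_inf, y_sup] and widens the prediction
interval proportionally:

    y_hat   = sum_i m_i y_i + m* (y_inf + y_sup) / 2
    y_lower = sum_i m_i y_i + m* y_inf
    y_upper = sum_i m_i y_i + m* y_sup

so y_upper - y_lower = m* (y_sup - y_inf) exactly.

Numerical notes: phi is clamped to <= 1 - 1e-12 so duplicated points cannot
make K vanish; the exclusion products prod_{h != i} are computed with
prefix/suffix cumulative products, never by dividing a total product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .distance import DistanceParams, NeighborSet, as_weight_vector, knn_search

__all__ = [
    "PHI_CAP",
    "TrainingSet",
    "MassAssignment",
    "Prediction",
    "discount",
    "compute_masses",
    "compute_masses_full",
    "predict_point",
]

#: phi is capped strictly below 1 so that 1 - phi never vanishes even for
#: coincident points (otherwise K -> 0/0 for two neighbours at distance 0).
PHI_CAP = 1.0 - 1e-12


@dataclass
class TrainingSet:
    """The evidence set: min–max normalized features plus bounded targets.

    ``X`` holds training rows normalized per feature to [0, 1] using the
    stored ``feature_ranges`` (raw min, max). Queries are normalized with
    the same statistics and clipped into [0, 1]. ``y_inf``/``y_sup`` bound
    the observed targets and define the domain of the uncertainty mass.
    """

    X: NDArray[np.float64]
    y: NDArray[np.float64]
    y_inf: float
    y_sup: float
    feature_ranges: NDArray[np.float64]  # shape (q, 2): raw (min, max) per feature
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.feature_ranges = np.asarray(self.feature_ranges, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of rows")
        if self.X.shape[0] < 1:
            raise ValueError("training set must contain at least one row")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("training data contain non-finite entries")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_raw(
        cls,
        X_raw: ArrayLike,
        y: ArrayLike,
        feature_names: list[str] | None = None,
    ) -> "TrainingSet":
        """Build a training set from raw features, min–max scaling to [0, 1].

        Constant features (zero range) normalize to 0.
        """
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        lo = X_raw.min(axis=0)
        hi = X_raw.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        X = (X_raw - lo) / span
        return cls(
            X=X,
            y=y,
            y_inf=float(y.min()),
            y_sup=float(y.max()),
            feature_ranges=np.column_stack([lo, hi]),
            feature_names=list(feature_names) if feature_names else [],
        )

    def normalize_query(self, x: ArrayLike) -> NDArray[np.float64]:
        """Map a raw query into the training [0, 1] cube (values clipped)."""
        x = np.asarray(x, dtype=float)
        lo = self.feature_ranges[:, 0]
        hi = self.feature_ranges[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return np.clip((x - lo) / span, 0.0, 1.0)

    def raw_X(self) -> NDArray[np.float64]:
        """Recover the raw feature matrix from the stored normalization."""
        lo = self.feature_ranges[:, 0]
        hi = self.feature_ranges[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return self.X * span + lo


@dataclass(frozen=True)
class MassAssignment:
    """Per-neighbour masses plus the domain (ignorance) mass; sums to 1."""

    indices: NDArray[np.intp]
    neighbor_masses: NDArray[np.float64]
    domain_mass: float
    K: float

    def mass_of(self, row_id: int) -> float:
        """Mass of a training row; rows outside the neighbour set have mass 0."""
        hit = np.nonzero(self.indices == row_id)[0]
        return float(self.neighbor_masses[hit[0]]) if hit.size else 0.0

    def total(self) -> float:
        return float(self.neighbor_masses.sum() + self.domain_mass)


@dataclass(frozen=True)
class Prediction:
    """Pignistic point estimate with its uncertainty interval.

    ``uncertainty`` is the domain mass; the interval width equals
    ``uncertainty * (y_sup - y_inf)`` and ``y_hat`` is its midpoint.
    """

    y_hat: float
    y_lower: float
    y_upper: float
    uncertainty: float


def discount(d: ArrayLike, gamma: float, phi_form: str = "squared") -> NDArray | float:
    """Similarity of a training example at distance ``d`` (RBF discount).

    ``phi_form="squared"`` is the default exp(-d^2/gamma), the form implied
    by the analytic weight gradient; ``"linear"`` selects exp(-d/gamma^2).
    Values are clamped to <= 1 - 1e-12 (see module notes).
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if phi_form == "squared":
        val = np.exp(-(d * d) / gamma)
    elif phi_form == "linear":
        val = np.exp(-d / (gamma * gamma))
    else:
        raise ValueError(f"unknown phi_form {phi_form!r}")
    out = np.minimum(val, PHI_CAP)
    return float(out) if out.ndim == 0 else out


def _masses_from_phi(indices: NDArray, phi: NDArray) -> MassAssignment:
    # exclusion products prod_{h != i} (1 - phi_h) via prefix/suffix
    # cumulative products (exact even when a factor is at the clamp floor)
    F = 1.0 - phi
    prefix = np.concatenate([[1.0], np.cumprod(F)[:-1]])
    suffix = np.concatenate([np.cumprod(F[::-1])[:-1][::-1], [1.0]])
    excl = prefix * suffix
    u = phi * excl            # unnormalized neighbour masses
    P = np.prod(F)            # unnormalized domain mass
    K = P + u.sum()
    if not K > 0:
        raise RuntimeError("mass normalization constant K is not positive")
    return MassAssignment(
        indices=np.asarray(indices, dtype=np.intp),
        neighbor_masses=u / K,
        domain_mass=float(P / K),
        K=float(K),
    )


def compute_masses(
    x: ArrayLike,
    train: TrainingSet,
    neighbors: NeighborSet,
    w: ArrayLike | None = None,
    params: DistanceParams | None = None,
    phi_form: str = "squared",
) -> MassAssignment:
    """Dempster–Shafer masses of the k-NN evidence set for query ``x``.

    ``x`` is expected in normalized coordinates with the neighbour set drawn
    under the same weights and exponent; the stored neighbour distances are
    reused, so ``w`` only validates dimensions here.
    """
    params = params or DistanceParams()
    if w is not None:
        as_weight_vector(w, train.q)
    phi = np.asarray(discount(neighbors.distances, params.gamma, phi_form))
    return _masses_from_phi(neighbors.indices, phi)


def compute_masses_full(
    x: ArrayLike,
    train: TrainingSet,
    w: ArrayLike | None = None,
    params: DistanceParams | None = None,
    phi_form: str = "squared",
) -> MassAssignment:
    """Full-evidence-set masses: every training row is a neighbour (k = n)."""
    params = params or DistanceParams()
    wv = as_weight_vector(np.ones(train.q) if w is None else w, train.q)
    nb = knn_search(train.X, x, wv, k=train.n, p=params.p)
    return compute_masses(x, train, nb, wv, params, phi_form)


def predict_point(
    x: ArrayLike,
    train: TrainingSet,
    w: ArrayLike | None = None,
    k: int | None = None,
    params: DistanceParams | None = None,
    phi_form: str = "squared",
    *,
    normalized: bool = False,
    exclude: int | None = None,
) -> Prediction:
    """Pignistic prediction for one query: point estimate plus bounds.

    ``x`` is given in raw feature units unless ``normalized=True``. The
    prediction interval is centred on ``y_hat`` with half-width
    ``m* (y_sup - y_inf) / 2``; when evidence is absent (all phi -> 0) the
    estimate collapses to the domain midpoint with the full interval.
    """
    params = params or DistanceParams()
    if train.n < 1:
        raise ValueError("empty training set")
    wv = as_weight_vector(np.ones(train.q) if w is None else w, train.q)
    xq = np.asarray(x, dtype=float) if normalized else train.normalize_query(x)
    kk = train.n if k is None else k
    nb = knn_search(train.X, xq, wv, k=kk, p=params.p, exclude=exclude)
    ma = compute_masses(xq, train, nb, wv, params, phi_form)
    if exclude is not None:
        keep = np.ones(train.n, dtype=bool)
        keep[exclude] = False
        y_inf, y_sup = float(train.y[keep].min()), float(train.y[keep].max())
    else:
        y_inf, y_sup = train.y_inf, train.y_sup
    evid = float(np.sum(ma.neighbor_masses * train.y[ma.indices]))
    y_hat = evid + ma.domain_mass * 0.5 * (y_inf + y_sup)
    half = ma.domain_mass * 0.5 * (y_sup - y_inf)
    return Prediction(
        y_hat=y_hat,
        y_lower=y_hat - half,
        y_upper=y_hat + half,
        uncertainty=ma.domain_mass,
    )
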