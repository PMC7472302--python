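"""Seedable synthetic regression benchmarks (sparse linear and Friedman #1).

Two families, both with 5 informative features padded by irrelevant ones
and additive Gaussian noise of standard deviation 1 on the target:

* ``linear`` — a random sparse linear model: Gaussian design, exactly
  ``n_informative`` nonzero coefficients (the leading columns), built on
  :func:`sklearn.datasets.make_regression`. The stored feature matrix is
  min–max normalized to [0, 1]; the response is computed from the Gaussian
  design (min–max scaling is affine per feature, so the response stays
  exactly linear in the stored features).
* ``friedman`` — the Friedman #1 function
  f(x) = 10 sin(pi x0 x1) + 20 (x2 - 0.5)^2 + 10 x3 + 5 x4
  with all inputs uniform on [0, 1] and only the first five entering the
  response, via :func:`sklearn.datasets.make_friedman1`.

With ``scale_output`` the target is min–max scaled to [0, 1] over the
generated sample (so metrics are comparable across estimators and folds;
fold splits inherit this full-sample target scaling). Generators are pure
functions of their spec: the same spec always yields the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.datasets import make_friedman1, make_regression

from .core import TrainingSet

__all__ = [
    "SyntheticSpec",
    "friedman_response",
    "make_friedman",
    "make_linear",
    "generate",
    "TABLE_PRESETS",
    "FEATURE_SWEEP",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    family: str  # "linear" or "friedman"
    n_samples: int = 200
    n_features: int = 500
    n_informative: int = 5
    noise_sd: float = 1.0
    seed: int = 0
    scale_output: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "friedman"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.family == "friedman" and self.n_features < 5:
            raise ValueError("the Friedman response needs at least 5 features")


#: the four benchmark configurations: 200/5000 samples x linear/friedman,
#: 500 total features of which 5 are informative, noise sd 1, scaled output
TABLE_PRESETS: dict[str, SyntheticSpec] = {
    "linear-200": SyntheticSpec("linear", 200, 500),
    "friedman-200": SyntheticSpec("friedman", 200, 500),
    "linear-5000": SyntheticSpec("linear", 5000, 500),
    "friedman-5000": SyntheticSpec("friedman", 5000, 500),
}

#: feature-count sweep grid (50–1000 total features) for robustness curves
FEATURE_SWEEP: list[int] = [50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]


def friedman_response(x: ArrayLike) -> NDArray[np.float64] | float:
    """Noiseless Friedman #1 response of one vector or a row matrix.

    Only the first five coordinates enter:
    10 sin(pi x0 x1) + 20 (x2 - 0.5)^2 + 10 x3 + 5 x4.
    """
    x = np.asarray(x, dtype=float)
    vec = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] < 5:
        raise ValueError(f"need at least 5 features, got {X.shape[1]}")
    y = (10.0 * np.sin(np.pi * X[:, 0] * X[:, 1])
         + 20.0 * (X[:, 2] - 0.5) ** 2
         + 10.0 * X[:, 3]
         + 5.0 * X[:, 4])
    return float(y[0]) if vec else y


def _finalize(X_raw: NDArray, y: NDArray, spec: SyntheticSpec) -> TrainingSet:
    if spec.scale_output:
        lo, hi = y.min(), y.max()
        if hi > lo:
            y = (y - lo) / (hi - lo)
        else:
            y = np.zeros_like(y)
    return TrainingSet.from_raw(X_raw, y)


def make_friedman(spec: SyntheticSpec) -> TrainingSet:
    """Generate a Friedman #1 dataset per the spec (reproducible per seed)."""
    if spec.family != "friedman":
        raise ValueError("spec.family must be 'friedman'")
    X, y = make_friedman1(n_samples=spec.n_samples, n_features=spec.n_features,
                          noise=spec.noise_sd, random_state=spec.seed)
    return _finalize(X, y, spec)


def make_linear(spec: SyntheticSpec) -> TrainingSet:
    """Generate a random sparse linear dataset per the spec.

    The informative coefficients sit on the first ``n_informative`` columns
    (no column shuffling), so relevant-feature indices are known.
    """
    if spec.family != "linear":
        raise ValueError("spec.family must be 'linear'")
    X, y = make_regression(n_samples=spec.n_samples, n_features=spec.n_features,
                           n_informative=spec.n_informative, noise=spec.noise_sd,
                           shuffle=False, random_state=spec.seed)
    return _finalize(X, y, spec)


def generate(spec: SyntheticSpec) -> TrainingSet:
    """Dispatch on ``spec.family``."""
    return make_friedman(spec) if spec.family == "friedman" else make_linear(spec)


def spec_metadata(spec: SyntheticSpec) -> dict:
    """Provenance sidecar content for a generated table."""
    return {"generator": "wevreg.synthetic", "spec": asdict(spec)}
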