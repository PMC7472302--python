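"""High-level estimator objects tying the metric, masses and fit together.

:class:`EvidentialRegression` is the full model: learn per-feature weights
on the training data, then answer queries with the Pignistic expectation
and its uncertainty interval. :class:`WeightedKNNRegression` is the
kernel-mean ablation sharing the same metric and weight-learning loop.
Both follow the familiar fit/predict idiom on raw feature matrices.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

from . import _engine as eng
from .core import TrainingSet
from .learning import FitConfig, FitResult, fit_weights, select_gamma

__all__ = ["EvidentialRegression", "WeightedKNNRegression", "make_estimator"]


class _WeightedEstimator:
    _kind = ""

    def __init__(self, config: FitConfig | None = None, *, learn_weights: bool = True):
        self.config = config or FitConfig()
        self.learn_weights = learn_weights

    def fit(self, X: ArrayLike, y: ArrayLike,
            feature_names: list[str] | None = None) -> "_WeightedEstimator":
        """Normalize, resolve the discount radius, learn the weights."""
        self.train_ = TrainingSet.from_raw(X, y, feature_names)
        cfg = self.config
        gamma = cfg.gamma if cfg.gamma is not None else select_gamma(
            self.train_, cfg, self._kind)
        self.gamma_ = float(gamma)
        cfg = replace(cfg, gamma=self.gamma_)
        if self.learn_weights and self.train_.n >= 2:
            self.result_: FitResult | None = fit_weights(self.train_, cfg, self._kind)
            self.weights_ = self.result_.w_hat
        else:
            self.result_ = None
            self.weights_ = np.ones(self.train_.q)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "train_"):
            raise RuntimeError("estimator is not fitted")

    def _forward(self, X: ArrayLike) -> tuple[NDArray, NDArray]:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xq = np.clip((X - self.train_.feature_ranges[:, 0]) /
                     np.where(self.train_.feature_ranges[:, 1] >
                              self.train_.feature_ranges[:, 0],
                              self.train_.feature_ranges[:, 1] -
                              self.train_.feature_ranges[:, 0], 1.0),
                     0.0, 1.0)
        cfg = self.config
        return eng.batch_predict(Xq, self.train_.X, self.train_.y,
                                 self.weights_, cfg.k, self.gamma_, cfg.p,
                                 cfg.phi_form, self._kind,
                                 self.train_.y_inf, self.train_.y_sup)

    def predict(self, X: ArrayLike) -> NDArray[np.float64]:
        """Point predictions for raw-unit query rows."""
        return self._forward(X)[0]


class EvidentialRegression(_WeightedEstimator):
    """Weighted evidential (Dempster–Shafer) k-NN regressor."""

    _kind = "evreg"

    def predict_with_bounds(self, X: ArrayLike
                            ) -> tuple[NDArray, NDArray, NDArray, NDArray]:
        """Return (y_hat, y_lower, y_upper, uncertainty) per query row.

        The interval is centred on the point estimate with half-width
        ``uncertainty * (y_sup - y_inf) / 2``.
        """
        yhat, mstar = self._forward(X)
        half = mstar * 0.5 * (self.train_.y_sup - self.train_.y_inf)
        return yhat, yhat - half, yhat + half, mstar


class WeightedKNNRegression(_WeightedEstimator):
    """Kernel-weighted k-NN mean with the same learned metric (ablation)."""

    _kind = "wknn"


def make_estimator(name: str, config: FitConfig | None = None,
                   **kwargs) -> _WeightedEstimator:
    """Instantiate an estimator by short name ("wevreg" or "wknn")."""
    table = {"wevreg": EvidentialRegression, "wknn": WeightedKNNRegression}
    try:
        return table[name](config, **kwargs)
    except KeyError:
        raise ValueError(f"unknown estimator {name!r}; expected one of {sorted(table)}")
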