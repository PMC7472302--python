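"""Kernel-weighted k-NN regression baseline sharing the weighted metric.

The comparator predicts with a kernel-weighted mean of the k nearest
neighbours' targets,

    yhat(x) = (1/Z) sum_{x' in N(x)} y(x') exp(-d(x, x') / beta),
    Z = sum_{x' in N(x)} exp(-d(x, x') / beta),

where d is the same weighted Minkowski distance the evidential model uses
and beta plays the radius role (housed in ``FitConfig.gamma``). Unlike the
evidential model it carries no domain/ignorance mass, so its estimate is
always a convex combination of neighbour targets; ablating against it
isolates the contribution of the Dempster–Shafer mass combination. Its
feature weights are learned with the same leave-one-out descent loop.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from . import _engine as eng
from .core import TrainingSet
from .distance import as_weight_vector, knn_search
from .learning import FitConfig, FitResult, fit_weights

__all__ = ["wknn_predict", "wknn_fit"]


def wknn_predict(x: ArrayLike, train: TrainingSet, w: ArrayLike | None = None,
                 cfg: FitConfig | None = None, *, normalized: bool = False) -> float:
    """Kernel-weighted mean of the k nearest neighbours' targets.

    ``cfg.gamma`` is the kernel radius beta (the kernel uses the raw
    distance d, not d^2). The estimate always lies within the range of the
    neighbour targets.
    """
    cfg = cfg or FitConfig(gamma=1.0)
    if cfg.gamma is None:
        raise ValueError("wknn_predict requires an explicit kernel radius (cfg.gamma)")
    if train.n < 1:
        raise ValueError("empty training set")
    wv = as_weight_vector(np.ones(train.q) if w is None else w, train.q)
    xq = np.asarray(x, dtype=float) if normalized else train.normalize_query(x)
    nb = knn_search(train.X, xq, wv, k=cfg.k, p=cfg.p)
    yhat, _ = eng.wknn_forward(nb.distances[None, :], train.y[nb.indices][None, :],
                               cfg.gamma, want_grad=False)
    return float(yhat[0])


def wknn_fit(train: TrainingSet, cfg: FitConfig) -> FitResult:
    """Learn per-feature weights for the kernel k-NN baseline.

    Same epoch loop as the evidential fit (leave-one-out MSE, analytic
    gradient through the kernel mean, optimizer step, clip to >= 0).
    """
    return fit_weights(train, cfg, kind="wknn")
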