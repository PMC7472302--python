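"""Evaluation metrics and the repeated k-fold validation protocol.

Metrics are the standard trio for cost-style regression:

    MAE  = (1/n) sum |yhat_i - y_i|
    MAPE = (1/n) sum |yhat_i - y_i| / y_i          (undefined at y_i = 0)
    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

The evaluation protocol is k-fold cross-validation repeated several times
with fresh shuffles (default 5 folds x 5 repetitions = 25 validations);
summaries report the median and standard deviation of each metric across
all validation folds. Any hyperparameter search an estimator performs
(e.g. the discount-radius grid) happens inside its ``fit`` on the training
folds only, so no information leaks from the validation folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.model_selection import KFold

from .core import TrainingSet

logger = logging.getLogger(__name__)

__all__ = ["mae", "mape", "r_squared", "EvalReport", "repeated_kfold_evaluate"]


def _pair(y_hat: ArrayLike, y: ArrayLike) -> tuple[NDArray, NDArray]:
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.size != y.size:
        raise ValueError(f"length mismatch: {y_hat.size} predictions vs {y.size} targets")
    return y_hat, y


def mae(y_hat: ArrayLike, y: ArrayLike) -> float:
    """Mean absolute error."""
    y_hat, y = _pair(y_hat, y)
    return float(np.mean(np.abs(y_hat - y)))


def mape(y_hat: ArrayLike, y: ArrayLike) -> float:
    """Mean absolute percentage error; zero targets are an error."""
    y_hat, y = _pair(y_hat, y)
    zeros = np.nonzero(y == 0)[0]
    if zeros.size:
        raise ValueError(f"MAPE is undefined for zero targets at rows {zeros.tolist()}")
    return float(np.mean(np.abs(y_hat - y) / np.abs(y)))


def r_squared(y_hat: ArrayLike, y: ArrayLike) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_hat, y = _pair(y_hat, y)
    if y.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for a constant target")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


_METRICS: dict[str, Callable[[ArrayLike, ArrayLike], float]] = {
    "mae": mae,
    "mape": mape,
    "r2": r_squared,
}


@dataclass
class EvalReport:
    """Per-fold metric values plus the median ± sd summary."""

    folds: int
    repetitions: int
    seed: int
    fold_records: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def values(self, metric: str) -> NDArray[np.float64]:
        return np.array([rec[metric] for rec in self.fold_records])

    def summary(self) -> dict[str, dict[str, float]]:
        """``{metric: {"median": ..., "sd": ...}}`` across all folds."""
        out: dict[str, dict[str, float]] = {}
        if not self.fold_records:
            return out
        for metric in self.fold_records[0]:
            if metric in ("repetition", "fold"):
                continue
            vals = self.values(metric)
            out[metric] = {"median": float(np.median(vals)),
                           "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0}
        return out


def repeated_kfold_evaluate(
    data: TrainingSet | tuple[ArrayLike, ArrayLike],
    estimator_factory: Callable[[], object],
    folds: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    metrics: tuple[str, ...] = ("mae", "r2"),
) -> EvalReport:
    """Repeated k-fold evaluation of an estimator factory.

    ``data`` is either a :class:`TrainingSet` (its raw features are
    recovered so each training fold re-derives its own normalization) or a
    raw ``(X, y)`` pair. ``estimator_factory`` returns a fresh object with
    ``fit(X, y)`` and ``predict(X)`` per fold. Each repetition shuffles
    with its own sub-seed, so every row lands in exactly one validation
    fold per repetition. A failing fold is recorded in ``report.failures``
    and surfaced as a warning, never silently dropped. MAPE is not in the
    default metric set: min–max-scaled targets contain an exact zero.
    """
    if isinstance(data, TrainingSet):
        X, y = data.raw_X(), data.y
    else:
        X = np.atleast_2d(np.asarray(data[0], dtype=float))
        y = np.asarray(data[1], dtype=float).ravel()
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold validation")
    for m in metrics:
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}; expected subset of {sorted(_METRICS)}")
    rep_seeds = np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)
    report = EvalReport(folds=folds, repetitions=repetitions, seed=seed)
    for rep in range(repetitions):
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(rep_seeds[rep]))
        for fold, (tr, va) in enumerate(kf.split(X)):
            try:
                est = estimator_factory()
                est.fit(X[tr], y[tr])
                y_hat = est.predict(X[va])
                rec = {"repetition": rep, "fold": fold}
                rec.update({m: _METRICS[m](y_hat, y[va]) for m in metrics})
                report.fold_records.append(rec)
            except Exception as exc:  # noqa: BLE001 — recorded and surfaced
                report.failures.append(
                    {"repetition": rep, "fold": fold, "error": repr(exc)})
                warnings.warn(
                    f"fold {fold} of repetition {rep} failed: {exc!r}",
                    stacklevel=2)
    return report
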