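"""Table readers/writers and versioned model persistence.

Data travel as UTF-8 CSV with a header row and '.' decimals; models are a
plain-JSON artifact carrying everything a lazy learner needs to predict:
the stored evidence (features and targets), normalization ranges, learned
weights and hyperparameters. JSON float serialization round-trips exactly
(shortest-repr), so save -> load -> predict is bit-identical to predicting
in memory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .learning import FitConfig
from .models import EvidentialRegression, WeightedKNNRegression, _WeightedEstimator

logger = logging.getLogger(__name__)

MODEL_FORMAT = "wevreg-model/1"

__all__ = ["RawTable", "read_table", "write_table", "save_model", "load_model"]


@dataclass
class RawTable:
    """A parsed delimited table split into features and target."""

    X: NDArray[np.float64]
    y: NDArray[np.float64]
    feature_names: list[str]
    target_name: str


def read_table(path: str | Path, target: str = "y",
               impute_median: bool = False) -> RawTable:
    """Read a CSV with a header row into features plus one numeric target.

    Column order is preserved. Non-numeric or missing cells are rejected
    with their (1-based) data row numbers; with ``impute_median`` missing
    *feature* cells are filled with the column median instead (missing
    targets always reject).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if target not in df.columns:
        raise ValueError(f"target column {target!r} not found in {path.name} "
                         f"(columns: {list(df.columns)})")
    if len(df) == 0:
        raise ValueError(f"{path.name} contains a header but no data rows")
    num = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = num.isna() & df.notna()
    if non_numeric.any().any():
        rows = sorted(int(r) + 1 for r in set(non_numeric.any(axis=1).to_numpy().nonzero()[0]))
        raise ValueError(f"non-numeric cells at data rows {rows}")
    if num[target].isna().any():
        rows = sorted(int(r) + 1 for r in num[target].isna().to_numpy().nonzero()[0])
        raise ValueError(f"missing target values at data rows {rows}")
    feats = num.drop(columns=[target])
    if feats.isna().any().any():
        if impute_median:
            feats = feats.fillna(feats.median())
            logger.info("imputed missing feature cells with column medians")
        else:
            rows = sorted(int(r) + 1 for r in set(feats.isna().any(axis=1).to_numpy().nonzero()[0]))
            raise ValueError(
                f"missing feature values at data rows {rows} "
                "(pass impute_median=True to fill with column medians)")
    return RawTable(X=feats.to_numpy(dtype=float), y=num[target].to_numpy(dtype=float),
                    feature_names=list(feats.columns), target_name=target)


def write_table(path: str | Path, X: NDArray, y: NDArray,
                feature_names: list[str] | None = None,
                target_name: str = "y") -> None:
    """Write features plus target as CSV with a header row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df[target_name] = np.asarray(y, dtype=float).ravel()
    df.to_csv(path, index=False)


def save_model(path: str | Path, model: _WeightedEstimator,
               target_transform: str = "identity") -> None:
    """Persist a fitted estimator as a versioned JSON artifact."""
    model._check_fitted()
    tr = model.train_
    cfg = model.config
    payload = {
        "format": MODEL_FORMAT,
        "estimator": model._kind,
        "feature_names": tr.feature_names,
        "feature_min": tr.feature_ranges[:, 0].tolist(),
        "feature_max": tr.feature_ranges[:, 1].tolist(),
        "X_normalized": tr.X.tolist(),
        "y": tr.y.tolist(),
        "y_inf": tr.y_inf,
        "y_sup": tr.y_sup,
        "weights": np.asarray(model.weights_).tolist(),
        "gamma": model.gamma_,
        "k": cfg.k,
        "p": cfg.p,
        "phi_form": cfg.phi_form,
        "alpha": cfg.alpha,
        "num_epochs": cfg.num_epochs,
        "optimizer": cfg.optimizer,
        "seed": cfg.seed,
        "target_transform": target_transform,
        "loss_history": (model.result_.loss_history.tolist()
                         if model.result_ is not None else []),
        "best_epoch": (model.result_.best_epoch
                       if model.result_ is not None else None),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> _WeightedEstimator:
    """Reconstruct a fitted estimator from its JSON artifact."""
    payload = json.loads(Path(path).read_text())
    fmt = payload.get("format")
    if fmt != MODEL_FORMAT:
        raise ValueError(f"unsupported model format {fmt!r} (expected {MODEL_FORMAT})")
    cls = {"evreg": EvidentialRegression, "wknn": WeightedKNNRegression}[payload["estimator"]]
    cfg = FitConfig(k=payload["k"], alpha=payload["alpha"],
                    num_epochs=payload["num_epochs"], gamma=payload["gamma"],
                    p=payload["p"], optimizer=payload["optimizer"],
                    seed=payload["seed"], phi_form=payload["phi_form"])
    model = cls(cfg)
    from .core import TrainingSet  # local import to avoid a cycle at module load

    model.train_ = TrainingSet(
        X=np.array(payload["X_normalized"], dtype=float),
        y=np.array(payload["y"], dtype=float),
        y_inf=payload["y_inf"],
        y_sup=payload["y_sup"],
        feature_ranges=np.column_stack([payload["feature_min"], payload["feature_max"]]),
        feature_names=list(payload["feature_names"]),
    )
    model.gamma_ = float(payload["gamma"])
    model.weights_ = np.array(payload["weights"], dtype=float)
    model.result_ = None
    model.target_transform = payload.get("target_transform", "identity")
    return model
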