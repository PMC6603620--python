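"""Validation and test metrics: k-fold cross-validated RMSE, per-beverage
aggregation, percent error, and the normative +/-0.5 % v/v tolerance check.

Cross-validation is record-level by default (each 1-second record is one
example); grouped measurement-level folding is available because record-level
folds leak within-measurement autocorrelation.  The pooled CV RMSE is the RMSE
over the concatenated held-out predictions, not the mean of per-fold RMSEs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from .errors import ConfigError, DomainError, SchemaError
from .regression import FittedModel, predict

__all__ = [
    "CVConfig",
    "EvaluationReport",
    "kfold_indices",
    "cross_validate",
    "rmse",
    "aggregate_by_sample",
    "percent_error",
    "tolerance_check",
    "build_report",
]

#: Normative labeling tolerance on declared alcohol content (% v/v).
NORMATIVE_TOLERANCE = 0.5


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    shuffle: bool = True
    grouped: bool = False  # fold by measurement instead of by record

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")


def kfold_indices(n: int, cfg: CVConfig) -> list[np.ndarray]:
    """Disjoint held-out index sets covering 0..n-1, sizes differing by <= 1."""
    if cfg.k > n:
        raise ConfigError(f"k ({cfg.k}) exceeds number of records ({n})")
    splitter = KFold(
        n_splits=cfg.k,
        shuffle=cfg.shuffle,
        random_state=cfg.seed if cfg.shuffle else None,
    )
    return [test for _, test in splitter.split(np.zeros(n))]


def rmse(predicted, actual) -> float:
    """Root-mean-square prediction error."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size == 0 or p.shape != a.shape:
        raise ConfigError("rmse needs equally sized, non-empty inputs")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def cross_validate(
    model_factory: Callable[[pd.DataFrame, np.ndarray], FittedModel],
    X: pd.DataFrame,
    y,
    cfg: CVConfig,
    groups: Sequence | None = None,
) -> float:
    """Pooled k-fold RMSE: train on each fold's complement, predict the
    held-out records, and take the RMSE over all held-out predictions."""
    y = np.asarray(y, dtype=float)
    n = len(X)
    held_out_pred = np.empty(n)
    if cfg.grouped:
        if groups is None:
            raise ConfigError("grouped CV requires group labels")
        splits = GroupKFold(n_splits=cfg.k).split(X, y, groups=np.asarray(groups))
    else:
        splits = (
            (np.setdiff1d(np.arange(n), test), test)
            for test in kfold_indices(n, cfg)
        )
    for train_idx, test_idx in splits:
        model = model_factory(X.iloc[train_idx], y[train_idx])
        held_out_pred[test_idx] = predict(model, X.iloc[test_idx])
    return rmse(held_out_pred, y)


def aggregate_by_sample(record_predictions, sample_ids) -> pd.Series:
    """Arithmetic mean of record-level predictions per beverage, pooling all
    bottles of that beverage."""
    preds = np.asarray(record_predictions, dtype=float)
    ids = pd.Series(np.asarray(sample_ids), name="sample_id")
    if len(preds) != len(ids):
        raise SchemaError("predictions and sample ids differ in length")
    return pd.Series(preds).groupby(ids.values).mean()


def percent_error(prediction: float, labeled: float) -> float:
    """|prediction - labeled| / labeled * 100."""
    if labeled <= 0:
        raise DomainError(f"labeled content must be positive, got {labeled}")
    return abs(prediction - labeled) / labeled * 100.0


def tolerance_check(
    prediction: float, labeled: float, tol: float = NORMATIVE_TOLERANCE
) -> bool:
    """True iff the prediction is within the normative labeling tolerance."""
    return bool(abs(prediction - labeled) <= tol)


@dataclass
class EvaluationReport:
    """Per-model RMSEs and per-beverage predictions/errors/tolerance flags."""

    model_metrics: dict[str, dict[str, float]]
    beverages: pd.DataFrame  # model, sample_id, labeled_abv, predicted_abv, ...
    tolerance: float = NORMATIVE_TOLERANCE
    provenance: dict = field(default_factory=dict)

    def rmse_table(self) -> pd.DataFrame:
        """One row per model: validation (k-fold) and test RMSE."""
        rows = [
            {
                "model": kind,
                "rmse_validation": m["rmse_validation"],
                "rmse_test": m["rmse_test_record"],
            }
            for kind, m in self.model_metrics.items()
        ]
        return pd.DataFrame(rows)

    def percent_error_table(self) -> pd.DataFrame:
        """Wide table: one row per model, one column per beverage plus the
        unweighted average percent error."""
        wide = self.beverages.pivot(
            index="model", columns="sample_id", values="percent_error"
        )
        wide["Average"] = wide.mean(axis=1)
        return wide.reset_index().rename_axis(None, axis=1)

    def to_dict(self) -> dict:
        return {
            "model_metrics": self.model_metrics,
            "beverages": self.beverages.to_dict(orient="records"),
            "tolerance": self.tolerance,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvaluationReport":
        return cls(
            model_metrics={k: dict(v) for k, v in d["model_metrics"].items()},
            beverages=pd.DataFrame(d["beverages"]),
            tolerance=float(d["tolerance"]),
            provenance=dict(d.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(s))


def build_report(
    model_factories: Mapping[str, Callable[[pd.DataFrame, np.ndarray], FittedModel]],
    X_calib: pd.DataFrame,
    y_calib,
    X_test: pd.DataFrame,
    test_labels,
    test_sample_ids,
    cv_cfg: CVConfig,
    tolerance: float = NORMATIVE_TOLERANCE,
    calib_groups: Sequence | None = None,
    provenance: Mapping | None = None,
) -> EvaluationReport:
    """Cross-validate, refit and test every model kind; assemble the report.

    ``test_labels`` are the labeled contents per record; per-beverage rows
    aggregate record predictions over both bottles, then compare against the
    labeled content with percent error and the tolerance flag.
    """
    y_calib = np.asarray(y_calib, dtype=float)
    test_labels = np.asarray(test_labels, dtype=float)
    labeled_by_sample = (
        pd.Series(test_labels).groupby(np.asarray(test_sample_ids)).first()
    )
    model_metrics: dict[str, dict[str, float]] = {}
    beverage_rows = []
    for kind, factory in model_factories.items():
        rmse_val = cross_validate(factory, X_calib, y_calib, cv_cfg, groups=calib_groups)
        model = factory(X_calib, y_calib)
        preds = predict(model, X_test)
        agg = aggregate_by_sample(preds, test_sample_ids)
        errors = {}
        for sample, pred in agg.items():
            labeled = float(labeled_by_sample[sample])
            err = percent_error(float(pred), labeled)
            errors[sample] = err
            beverage_rows.append(
                {
                    "model": kind,
                    "sample_id": sample,
                    "labeled_abv": labeled,
                    "predicted_abv": float(pred),
                    "percent_error": err,
                    "within_tolerance": tolerance_check(float(pred), labeled, tolerance),
                }
            )
        agg_labels = labeled_by_sample.loc[agg.index].to_numpy()
        model_metrics[kind] = {
            "rmse_validation": rmse_val,
            "rmse_test_record": rmse(preds, test_labels),
            "rmse_test_aggregate": rmse(agg.to_numpy(), agg_labels),
            "mean_percent_error": float(np.mean(list(errors.values()))),
            "r2_train": model.r2 if model.r2 is not None else float("nan"),
        }
    beverages = pd.DataFrame(beverage_rows)
    return EvaluationReport(
        model_metrics=model_metrics,
        beverages=beverages,
        tolerance=tolerance,
        provenance=dict(provenance or {}),
    )
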