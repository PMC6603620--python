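"""The four calibration regressors and the predictor-significance pruning step.

The regression target is the ethanol fraction (% v/v); predictors are the
normalized compensated resistances of the sensor channels.

* MLR — ordinary least squares with intercept (statsmodels).
* MNLR — OLS after a logarithmic transform ``x -> log(x + log_offset)`` of
  every predictor (the sensor response saturates at high alcohol contents,
  which the log linearizes); transforming the response instead is available
  as a config switch.
* ELM — extreme learning machine: a single hidden layer with input weights
  and biases drawn once from Uniform(-1, 1) and frozen, identity ("purelin")
  activation by default, and minimum-norm least-squares output weights via a
  tolerance-cut pseudoinverse.
* RF — random forest with 500 trees, 4 candidate predictors per split, leaf
  minimum of 5, bootstrap resampling, no pruning (scikit-learn).

Predictor pruning fits OLS of the target on all channels plus intercept and
removes every channel whose coefficient t-test p-value exceeds alpha = 0.05
(equivalently the 1-df partial F-test at 95% confidence); the surviving set is
used identically by all four regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor

from .errors import CollinearityError, ConfigError, DomainError, SchemaError

__all__ = [
    "SignificanceReport",
    "ModelConfig",
    "FittedModel",
    "sensor_significance",
    "fit_mlr",
    "fit_mnlr",
    "fit_elm",
    "fit_rf",
    "predict",
    "model_to_dict",
    "model_from_dict",
    "MODEL_KINDS",
]

MODEL_KINDS = ("MLR", "MNLR", "ELM", "RF")

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "purelin": lambda z: z,
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}

#: Relative singular-value cut for rank decisions and the ELM output solve.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class SignificanceReport:
    """Outcome of the per-sensor coefficient test at level ``alpha``.

    A sensor is removed exactly when its p-value exceeds alpha; retained and
    removed partition the input sensor set.
    """

    p_values: Mapping[str, float]
    alpha: float
    retained: tuple[str, ...]
    removed: tuple[str, ...]

    @classmethod
    def from_pvalues(cls, p_values: Mapping[str, float], alpha: float) -> "SignificanceReport":
        retained = tuple(s for s, p in p_values.items() if p <= alpha)
        removed = tuple(s for s, p in p_values.items() if p > alpha)
        return cls(dict(p_values), alpha, retained, removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensor": list(self.p_values),
                "p_value": [self.p_values[s] for s in self.p_values],
                "retained": [s in self.retained for s in self.p_values],
            }
        )


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for the four regressor kinds (unused fields ignored)."""

    nhid: int = 15
    actfun: str = "purelin"
    log_offset: float = 0.1
    mnlr_transform: str = "predictors"  # or "response"
    ntree: int = 500
    mtry: int = 4
    min_leaf: int = 5
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nhid < 1:
            raise ConfigError("nhid must be >= 1")
        if self.ntree < 1:
            raise ConfigError("ntree must be >= 1")
        if self.log_offset <= 0:
            raise ConfigError("log_offset must be positive")
        if self.actfun not in _ACTIVATIONS:
            raise ConfigError(
                f"unknown activation {self.actfun!r}; choose from {sorted(_ACTIVATIONS)}"
            )
        if self.mnlr_transform not in ("predictors", "response"):
            raise ConfigError("mnlr_transform must be 'predictors' or 'response'")


@dataclass
class FittedModel:
    """A fitted regressor with a uniform prediction contract.

    ``params`` is JSON-serializable for MLR/MNLR/ELM; RF keeps the fitted
    scikit-learn ensemble in ``estimator`` and exports a tree-array structure
    on serialization.  Features bind by name, not position.
    """

    kind: str
    feature_names: tuple[str, ...]
    params: dict
    r2: float | None = None
    r2_adj: float | None = None
    estimator: Any = field(default=None, repr=False, compare=False)


def _design_with_intercept(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming dependent columns if A is numerically
    rank-deficient (relative singular-value cut RANK_RTOL)."""
    s = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    if rank < A.shape[1]:
        _, _, piv = scipy.linalg.qr(A, pivoting=True, mode="economic")
        labels = ["(intercept)"] + names
        dependent = [labels[j] for j in piv[rank:]]
        raise CollinearityError(
            f"design matrix numerically rank-deficient (rank {rank} of "
            f"{A.shape[1]}); dependent columns: {dependent}"
        )


def sensor_significance(
    X: pd.DataFrame, y, alpha: float = 0.05
) -> SignificanceReport:
    """OLS of y on all sensors + intercept; per-sensor coefficient t-test.

    Requires more records than predictors + 1 and a numerically full-rank
    design (t-tests are undefined otherwise, e.g. on zero-noise data).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ConfigError(f"need more than {p + 1} records, got {n}")
    A = _design_with_intercept(X)
    _check_rank(A, list(X.columns))
    res = sm.OLS(y, A).fit()
    p_values = {name: float(res.pvalues[j + 1]) for j, name in enumerate(X.columns)}
    return SignificanceReport.from_pvalues(p_values, alpha)


def _ols_fit(X: pd.DataFrame, y: np.ndarray, rank_check: bool) -> tuple[dict, float, float]:
    A = _design_with_intercept(X)
    if rank_check:
        _check_rank(A, list(X.columns))
    res = sm.OLS(y, A).fit()
    params = {
        "intercept": float(res.params[0]),
        "coef": {name: float(res.params[j + 1]) for j, name in enumerate(X.columns)},
    }
    return params, float(res.rsquared), float(res.rsquared_adj)


def fit_mlr(X: pd.DataFrame, y, *, rank_check: bool = True) -> FittedModel:
    """Multiple linear regression with intercept.

    With ``rank_check=False`` a numerically rank-deficient design is solved
    by the minimum-norm pseudoinverse instead of raising (needed e.g. for
    noise-free synthetic data, where smooth channels are collinear).
    """
    y = np.asarray(y, dtype=float)
    if len(X) <= X.shape[1] + 1:
        raise ConfigError("need more records than predictors + 1")
    params, r2, r2_adj = _ols_fit(X, y, rank_check)
    return FittedModel("MLR", tuple(X.columns), params, r2, r2_adj)


def fit_mnlr(
    X: pd.DataFrame, y, config: ModelConfig = ModelConfig(), *, rank_check: bool = True
) -> FittedModel:
    """OLS after the logarithmic transform of every predictor (default) or of
    the response (``config.mnlr_transform='response'``)."""
    y = np.asarray(y, dtype=float)
    off = config.log_offset
    if config.mnlr_transform == "predictors":
        if (X.to_numpy(dtype=float) <= -off).any():
            raise DomainError(
                f"predictor value <= -log_offset ({-off}); log transform undefined"
            )
        Xt = np.log(X + off)
        yt = y
    else:
        if (y <= -off).any():
            raise DomainError("response value <= -log_offset; log transform undefined")
        Xt = X
        yt = np.log(y + off)
    params, r2, r2_adj = _ols_fit(Xt, yt, rank_check)
    params["log_offset"] = off
    params["transform"] = config.mnlr_transform
    return FittedModel("MNLR", tuple(X.columns), params, r2, r2_adj)


def fit_elm(X: pd.DataFrame, y, config: ModelConfig = ModelConfig()) -> FittedModel:
    """Extreme learning machine with frozen random input layer.

    Input weights (p x nhid) and hidden biases are drawn once from
    Uniform(-1, 1) seeded by ``config.seed``; output weights are the
    minimum-norm least-squares solution ``pinv(H) @ y`` with a relative
    singular-value cut of RANK_RTOL.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ConfigError("need at least 2 records")
    rng = np.random.default_rng(config.seed)
    p = X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(p, config.nhid))
    b = rng.uniform(-1.0, 1.0, size=config.nhid)
    act = _ACTIVATIONS[config.actfun]
    H = act(X.to_numpy(dtype=float) @ W + b)
    beta = np.linalg.pinv(H, rcond=RANK_RTOL) @ y
    fitted = H @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    n = len(y)
    r2_adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else float("nan")
    )
    params = {
        "weights": W.tolist(),
        "biases": b.tolist(),
        "output_weights": beta.tolist(),
        "actfun": config.actfun,
        "nhid": config.nhid,
        "seed": config.seed,
    }
    return FittedModel("ELM", tuple(X.columns), params, r2, r2_adj)


def fit_rf(X: pd.DataFrame, y, config: ModelConfig = ModelConfig()) -> FittedModel:
    """Random forest of unpruned regression trees on bootstrap resamples."""
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ConfigError("need at least 2 records")
    if config.mtry > X.shape[1]:
        raise ConfigError(
            f"mtry ({config.mtry}) exceeds number of predictors ({X.shape[1]})"
        )
    est = RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=config.mtry,
        min_samples_leaf=config.min_leaf,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X.to_numpy(dtype=float), y)
    fitted = est.predict(X.to_numpy(dtype=float))
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    params = {
        "ntree": config.ntree,
        "mtry": config.mtry,
        "min_leaf": config.min_leaf,
        "bootstrap": config.bootstrap,
        "seed": config.seed,
    }
    return FittedModel("RF", tuple(X.columns), params, r2, None, estimator=est)


def _aligned(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    missing = set(model.feature_names) - set(X.columns)
    if missing:
        raise SchemaError(f"prediction input missing features: {sorted(missing)}")
    return X.loc[:, list(model.feature_names)].to_numpy(dtype=float)


def _predict_trees(trees: list[dict], x: np.ndarray) -> np.ndarray:
    """Vectorized traversal of serialized trees (level-wise index chasing)."""
    total = np.zeros(len(x))
    for t in trees:
        left = np.asarray(t["children_left"])
        right = np.asarray(t["children_right"])
        feat = np.asarray(t["feature"])
        thr = np.asarray(t["threshold"])
        value = np.asarray(t["value"])
        idx = np.zeros(len(x), dtype=int)
        active = left[idx] != -1
        while active.any():
            f = feat[idx[active]]
            go_left = x[active, f] <= thr[idx[active]]
            idx[active] = np.where(go_left, left[idx[active]], right[idx[active]])
            active = left[idx] != -1
        total += value[idx]
    return total / len(trees)


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted % v/v per record; features bind by column name."""
    x = _aligned(model, X)
    if model.kind == "MLR":
        coef = np.array([model.params["coef"][n] for n in model.feature_names])
        return model.params["intercept"] + x @ coef
    if model.kind == "MNLR":
        coef = np.array([model.params["coef"][n] for n in model.feature_names])
        off = model.params["log_offset"]
        if model.params["transform"] == "predictors":
            if (x <= -off).any():
                raise DomainError("predictor value <= -log_offset at prediction time")
            return model.params["intercept"] + np.log(x + off) @ coef
        return np.exp(model.params["intercept"] + x @ coef) - off
    if model.kind == "ELM":
        W = np.asarray(model.params["weights"])
        b = np.asarray(model.params["biases"])
        beta = np.asarray(model.params["output_weights"])
        return _ACTIVATIONS[model.params["actfun"]](x @ W + b) @ beta
    if model.kind == "RF":
        if model.estimator is not None:
            return model.estimator.predict(x)
        return _predict_trees(model.params["trees"], x)
    raise ConfigError(f"unknown model kind {model.kind!r}")


def model_to_dict(model: FittedModel) -> dict:
    """JSON-serializable representation (RF exported as tree arrays)."""
    d = {
        "kind": model.kind,
        "feature_names": list(model.feature_names),
        "params": dict(model.params),
        "r2": model.r2,
        "r2_adj": model.r2_adj,
    }
    if model.kind == "RF" and model.estimator is not None:
        trees = []
        for est in model.estimator.estimators_:
            t = est.tree_
            trees.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "value": t.value.reshape(-1).tolist(),
                }
            )
        d["params"]["trees"] = trees
    return d


def model_from_dict(d: Mapping) -> FittedModel:
    return FittedModel(
        kind=d["kind"],
        feature_names=tuple(d["feature_names"]),
        params=dict(d["params"]),
        r2=d.get("r2"),
        r2_adj=d.get("r2_adj"),
    )
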