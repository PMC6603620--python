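"""Signal preprocessing: warm-up trim, gated moving average, compensation,
min-max normalization.

Stage order per channel is: trim residual warm-up, smooth the voltage with an
outlier-gated trailing moving average, convert voltage to resistance through
the divider, divide by the ambient polynomial, then min-max normalize with a
state frozen on the calibration data (test features are never clipped and may
fall outside [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateFeatureError,
    EmptyOutputError,
    SchemaError,
)
from .sensor_model import (
    DEFAULT_VCC,
    SensorSpec,
    compensate_series,
    voltage_to_resistance,
)

__all__ = [
    "FilterConfig",
    "NormalizationState",
    "trim_warmup",
    "gated_moving_average",
    "fit_normalizer",
    "apply_normalizer",
    "preprocess_pipeline",
]

_COVARIATE_COLUMNS = ("time_s", "temperature_c", "humidity_pct")


@dataclass(frozen=True)
class FilterConfig:
    """Outlier-gated moving average: trailing window of up to ``window`` raw
    samples; values further than ``gate_k`` window standard deviations from
    the window mean are excluded from the average (so between 1 and ``window``
    values are actually averaged at each index)."""

    window: int = 50
    gate_k: float = 3.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ConfigError(f"filter window must be >= 1, got {self.window}")
        if self.gate_k < 0:
            raise ConfigError("gate_k must be non-negative")


def trim_warmup(series: pd.Series, warmup_s: float) -> pd.Series:
    """Drop leading readings with time < ``warmup_s``.

    ``series`` is indexed by time in seconds.  Raises
    :class:`EmptyOutputError` if nothing would remain.
    """
    if warmup_s < 0:
        raise ConfigError("warmup_s must be non-negative")
    out = series[series.index >= warmup_s]
    if out.empty:
        raise EmptyOutputError(
            f"warm-up trim at {warmup_s} s leaves no data "
            f"(series ends at {series.index.max()} s)"
        )
    return out


def gated_moving_average(values, config: FilterConfig = FilterConfig()) -> np.ndarray:
    """Causal sigma-gated moving average; output length equals input length.

    For each index the trailing window of up to ``config.window`` raw values
    is taken; its mean mu and population standard deviation sigma are computed
    on the *full* raw window, then only values with ``|p - mu| <= gate_k *
    sigma`` enter the unweighted average.  A zero-sigma (constant) window is
    averaged whole.  The gated subset is never empty for ``gate_k >= 1``
    because at least one value always lies within one sigma of the mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise SchemaError("gated_moving_average expects a 1-D series")
    if x.size == 0:
        raise EmptyOutputError("empty series")
    w = config.window
    k = config.gate_k
    out = np.empty_like(x)

    head = min(w - 1, x.size)
    for i in range(head):  # ramp-up region with partial windows
        win = x[: i + 1]
        if win.max() == win.min():  # exactly constant window
            out[i] = win[0]
            continue
        mu = win.mean()
        sd = win.std()
        keep = np.abs(win - mu) <= k * sd
        out[i] = win[keep].mean() if keep.any() else mu
    if x.size >= w:
        wins = np.lib.stride_tricks.sliding_window_view(x, w)
        mu = wins.mean(axis=1)
        sd = wins.std(axis=1)
        keep = np.abs(wins - mu[:, None]) <= k * sd[:, None]
        keep[sd == 0] = True
        counts = keep.sum(axis=1)
        # guard against an empty gate (possible only for gate_k < 1)
        fallback = counts == 0
        counts = np.where(fallback, 1, counts)
        sums = np.where(keep, wins, 0.0).sum(axis=1)
        res = sums / counts
        res[fallback] = mu[fallback]
        constant = wins.max(axis=1) == wins.min(axis=1)
        res[constant] = wins[constant, 0]
        out[w - 1 :] = res
    return out


@dataclass(frozen=True)
class NormalizationState:
    """Frozen per-feature minima/maxima learned from calibration data."""

    feature_names: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": list(self.mins),
            "maxs": list(self.maxs),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationState":
        return cls(
            feature_names=tuple(d["feature_names"]),
            mins=tuple(float(v) for v in d["mins"]),
            maxs=tuple(float(v) for v in d["maxs"]),
        )


def fit_normalizer(features: pd.DataFrame) -> NormalizationState:
    """Learn per-feature min/max from training data only."""
    if len(features) < 2:
        raise ConfigError("need at least 2 records to fit a normalizer")
    mins = features.min(axis=0)
    maxs = features.max(axis=0)
    degenerate = [c for c in features.columns if maxs[c] == mins[c]]
    if degenerate:
        raise DegenerateFeatureError(
            f"feature(s) with max == min cannot be normalized: {degenerate}"
        )
    return NormalizationState(
        feature_names=tuple(features.columns),
        mins=tuple(float(mins[c]) for c in features.columns),
        maxs=tuple(float(maxs[c]) for c in features.columns),
    )


def apply_normalizer(state: NormalizationState, features: pd.DataFrame) -> pd.DataFrame:
    """(p - min) / (max - min) per feature; values outside the training range
    map outside [0, 1] and are deliberately not clipped."""
    missing = set(state.feature_names) - set(features.columns)
    if missing:
        raise SchemaError(f"features missing from input: {sorted(missing)}")
    x = features.loc[:, list(state.feature_names)]
    mins = np.asarray(state.mins)
    maxs = np.asarray(state.maxs)
    return (x - mins) / (maxs - mins)


def preprocess_pipeline(
    dataset: pd.DataFrame,
    registry: Mapping[str, SensorSpec],
    filter_cfg: FilterConfig = FilterConfig(),
    warmup_s: float = 0.0,
    *,
    v_cc: float = DEFAULT_VCC,
    state: NormalizationState | None = None,
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationState | None]:
    """Full per-record feature extraction.

    Per measurement and sensor channel: trim warm-up, gated moving average on
    the voltage, divider inversion to resistance, ambient compensation with
    that record's (temperature, humidity).  Features are then normalized with
    ``state`` if given (test data) or with a state freshly fitted on this
    dataset (calibration data); pass ``normalize=False`` to obtain raw
    compensated resistances.

    Returns ``(features, meta, state)`` where ``meta`` carries the retained
    records' ``label_abv``, ``sample_id`` and ``measurement_id``.
    """
    sensor_names = list(registry)
    required = set(sensor_names) | set(_COVARIATE_COLUMNS) | {
        "sample_id",
        "measurement_id",
        "label_abv",
    }
    missing = required - set(dataset.columns)
    if missing:
        raise SchemaError(f"dataset missing columns: {sorted(missing)}")

    feature_parts: list[pd.DataFrame] = []
    meta_parts: list[pd.DataFrame] = []
    for _, group in dataset.groupby("measurement_id", sort=False):
        group = group.sort_values("time_s")
        kept = group[group["time_s"] >= warmup_s]
        if kept.empty:
            raise EmptyOutputError(
                f"warm-up trim at {warmup_s} s leaves measurement "
                f"{group['measurement_id'].iloc[0]!r} empty"
            )
        temp = kept["temperature_c"].to_numpy(dtype=float)
        rh = kept["humidity_pct"].to_numpy(dtype=float)
        cols: dict[str, np.ndarray] = {}
        for name in sensor_names:
            spec = registry[name]
            v = gated_moving_average(kept[name].to_numpy(dtype=float), filter_cfg)
            r_s = voltage_to_resistance(v, spec, v_cc)
            cols[name] = np.asarray(compensate_series(spec, r_s, temp, rh))
        feature_parts.append(pd.DataFrame(cols, index=kept.index))
        meta_parts.append(kept[["label_abv", "sample_id", "measurement_id"]])

    features = pd.concat(feature_parts)
    meta = pd.concat(meta_parts)
    if normalize:
        if state is None:
            state = fit_normalizer(features)
        features = apply_normalizer(state, features)
    return features, meta, state
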