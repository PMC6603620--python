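"""MOS sensor registry and the voltage/resistance/compensation transforms.

A metal-oxide-semiconductor (MOS) gas sensor is read through a load-resistor
voltage divider: the sensing element of resistance ``Rs`` is in series with a
load resistor ``R_L`` (10 kOhm for every channel of this instrument) across the
supply ``v_cc``, and the output voltage is taken over the load.  ``Rs`` falls as
the reducing-gas concentration rises, so the output voltage rises with the gas
signal.

Because ``Rs`` also drifts with ambient temperature and relative humidity, each
sensor carries a quadratic ambient-response polynomial fitted to its datasheet
characteristic curves.  Dividing the measured resistance by that polynomial

    D(x0, x1) = alpha0*x0 + alpha1*x0**2 + beta0*x1 + beta1*x1**2
                + delta*x0*x1 + xi

(``x0`` temperature in deg C, ``x1`` relative humidity in %) yields the
temperature/humidity-compensated resistance used as the regression feature.
The 13 bundled channels and their polynomial constants ship as a versioned CSV
so they can be asserted bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AmbientEnvelopeError, ConfigError, InvalidReadingError, SchemaError

__all__ = [
    "SensorSpec",
    "CompensationInput",
    "compensation_denominator",
    "compensate",
    "compensate_series",
    "voltage_to_resistance",
    "resistance_to_voltage",
    "load_registry",
    "load_reference_pvalues",
    "DEFAULT_VCC",
]

#: Default supply voltage of the divider; standard for these sensor modules,
#: overridable everywhere it is consumed.
DEFAULT_VCC = 5.0

_REGISTRY_RESOURCE = "sensor_registry.csv"
_PVALUE_RESOURCE = "reference_sensor_pvalues.csv"
_EXPECTED_SENSOR_COUNT = 13


@dataclass(frozen=True)
class SensorSpec:
    """One MOS channel: identity, divider load, and ambient-compensation constants.

    ``fit_r2`` is the goodness of fit of the ambient polynomial to the
    manufacturer characteristic curves; it is informational metadata only and
    never enters any computation.
    """

    name: str
    sensitive_gases: tuple[str, ...]
    load_resistance: float
    alpha0: float
    alpha1: float
    beta0: float
    beta1: float
    delta: float
    xi: float
    fit_r2: float | None = None

    def __post_init__(self) -> None:
        if not self.load_resistance > 0:
            raise ConfigError(
                f"sensor {self.name!r}: load_resistance must be positive, "
                f"got {self.load_resistance}"
            )


@dataclass(frozen=True)
class CompensationInput:
    """A validated (resistance, temperature, humidity) triple for one record."""

    r_s: float
    x0: float
    x1: float

    def __post_init__(self) -> None:
        if self.r_s < 0:
            raise InvalidReadingError(f"negative resistance {self.r_s}")
        if not 0.0 <= self.x1 <= 100.0:
            raise ConfigError(f"relative humidity {self.x1} outside [0, 100] %")


def compensation_denominator(spec: SensorSpec, x0, x1):
    """Evaluate the ambient polynomial D(x0, x1) for one sensor.

    Accepts scalars or broadcastable arrays; pure arithmetic, never raises.
    The full six-term polynomial is always evaluated even though ``beta1`` and
    ``delta`` are zero for most bundled sensors.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    d = (
        spec.alpha0 * x0
        + spec.alpha1 * x0**2
        + spec.beta0 * x1
        + spec.beta1 * x1**2
        + spec.delta * x0 * x1
        + spec.xi
    )
    return d if d.ndim else float(d)


def compensate_series(spec: SensorSpec, r_s, x0, x1):
    """Compensated resistance ``r_s / D(x0, x1)`` for arrays of readings.

    Raises
    ------
    InvalidReadingError
        If any resistance is negative.
    AmbientEnvelopeError
        If the denominator is not strictly positive anywhere — the ambient
        conditions are outside the envelope the polynomial was calibrated on,
        and a negative compensated resistance would be meaningless.
    """
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s < 0):
        raise InvalidReadingError(f"sensor {spec.name!r}: negative resistance input")
    d = np.asarray(compensation_denominator(spec, x0, x1))
    if np.any(d <= 0):
        bad = np.argwhere(d <= 0)
        raise AmbientEnvelopeError(
            f"sensor {spec.name!r}: compensation denominator non-positive at "
            f"{bad.size} point(s) — conditions outside calibrated ambient envelope"
        )
    out = r_s / d
    return out if out.ndim else float(out)


def compensate(spec: SensorSpec, inp: CompensationInput) -> float:
    """Compensated resistance for a single validated record."""
    return float(compensate_series(spec, inp.r_s, inp.x0, inp.x1))


def voltage_to_resistance(v_out, spec: SensorSpec, v_cc: float = DEFAULT_VCC):
    """Invert the load-resistor divider: ``Rs = R_L * (v_cc - v_out) / v_out``.

    Strictly decreasing in ``v_out``.  Readings at or beyond the supply rails
    cannot come from a finite positive sensor resistance.
    """
    v_out = np.asarray(v_out, dtype=float)
    if np.any(v_out <= 0) or np.any(v_out >= v_cc):
        raise InvalidReadingError(
            f"sensor {spec.name!r}: output voltage outside (0, {v_cc}) V"
        )
    r = spec.load_resistance * (v_cc - v_out) / v_out
    return r if r.ndim else float(r)


def resistance_to_voltage(r_s, spec: SensorSpec, v_cc: float = DEFAULT_VCC):
    """Forward divider: ``v_out = v_cc * R_L / (R_L + Rs)``; used by the simulator."""
    r_s = np.asarray(r_s, dtype=float)
    if np.any(r_s < 0):
        raise InvalidReadingError(f"sensor {spec.name!r}: negative resistance")
    v = v_cc * spec.load_resistance / (spec.load_resistance + r_s)
    return v if v.ndim else float(v)


def _registry_from_frame(df: pd.DataFrame, source: str) -> dict[str, SensorSpec]:
    required = {
        "name",
        "sensitive_gases",
        "load_resistance_ohm",
        "alpha0",
        "alpha1",
        "beta0",
        "beta1",
        "delta",
        "xi",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{source}: missing registry columns {sorted(missing)}")
    if len(df) != _EXPECTED_SENSOR_COUNT:
        raise SchemaError(
            f"{source}: expected {_EXPECTED_SENSOR_COUNT} sensors, got {len(df)}"
        )
    if df["name"].duplicated().any():
        raise SchemaError(f"{source}: duplicated sensor names")
    registry: dict[str, SensorSpec] = {}
    for row in df.itertuples(index=False):
        spec = SensorSpec(
            name=row.name,
            sensitive_gases=tuple(str(row.sensitive_gases).split(";")),
            load_resistance=float(row.load_resistance_ohm),
            alpha0=float(row.alpha0),
            alpha1=float(row.alpha1),
            beta0=float(row.beta0),
            beta1=float(row.beta1),
            delta=float(row.delta),
            xi=float(row.xi),
            fit_r2=float(row.fit_r2) if "fit_r2" in df.columns else None,
        )
        if not spec.xi > 0:
            raise SchemaError(f"{source}: sensor {spec.name!r} has non-positive xi")
        registry[spec.name] = spec
    return registry


def load_registry(path: str | Path | None = None) -> dict[str, SensorSpec]:
    """Load the 13-sensor registry (bundled CSV by default), validating it.

    Returns an insertion-ordered mapping name -> :class:`SensorSpec`; the
    order defines the canonical channel order of dataset files.
    """
    if path is None:
        with resources.files("enose.data").joinpath(_REGISTRY_RESOURCE).open() as fh:
            df = pd.read_csv(fh)
        source = f"bundled {_REGISTRY_RESOURCE}"
    else:
        df = pd.read_csv(path)
        source = str(path)
    return _registry_from_frame(df, source)


def load_reference_pvalues() -> pd.Series:
    """Per-sensor p-values reported for the original prototype's calibration
    recordings, bundled so significance-threshold logic can be exercised
    against the instrument's published pruning outcome."""
    with resources.files("enose.data").joinpath(_PVALUE_RESOURCE).open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("name")["p_value"]
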