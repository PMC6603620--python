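"""Forward simulator for the sensor-array calibration and test protocol.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage of the pipeline is falsifiable without the original
laboratory recordings:

* a monotone power-law concentration response per channel,
  ``R_true(c) = r0 * (1 + k*c) ** (-gamma)`` — resistance falls, and hence
  divider voltage rises, with the ethanol fraction ``c`` (% v/v);
* multiplicative ambient confounding equal to the sensor's own compensation
  polynomial ``D(T, RH)``, so the compensation stage inverts it exactly;
* a first-order warm-up transient ``1 + exp(-(t + warmup_s)/tau)`` whose
  preheating portion (``warmup_s`` seconds) elapses before recording starts;
* multiplicative log-normal noise on resistance (resistances are positive);
  additive Gaussian noise on voltage is available as an option.

The calibration design is 15 ethanol/water standards measured once per
experiment, six experiments on three days at stated (temperature, humidity)
conditions, 8 min per measurement at 1 Hz.  The test design is 7 commercial
beers, two bottles each, at about 30 degC / 41 %RH; a beverage's non-ethanol
volatiles (e.g. the dark-malt beer) are lumped into a single multiplicative
``voc_multiplier`` on the concentration seen by the sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmbientEnvelopeError, ConfigError, DomainError
from .sensor_model import (
    SensorSpec,
    compensation_denominator,
    load_registry,
    resistance_to_voltage,
)

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_RUNS",
    "DEFAULT_RESPONSE",
    "ProtocolDesign",
    "BeverageSpec",
    "SimulationConfig",
    "default_beverages",
    "true_resistance",
    "simulate_measurement",
    "simulate_calibration_dataset",
    "simulate_test_dataset",
    "DATASET_COLUMNS",
]

#: The 15 calibration standards (% v/v ethanol in distilled water).
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (
    1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 3.7, 3.9, 4.1, 4.3, 4.5, 5.0, 5.5, 6.0, 8.0,
)

#: Six experiments, two per day, as (temperature degC, humidity %RH, pressure hPa).
#: Both same-day experiments share the stated day-level conditions.
DEFAULT_RUNS: tuple[tuple[float, float, float], ...] = (
    (25.0, 33.0, 1012.0),
    (25.0, 33.0, 1012.0),
    (25.0, 27.0, 1015.0),
    (25.0, 27.0, 1015.0),
    (27.0, 31.0, 1009.0),
    (27.0, 31.0, 1009.0),
)

# Per-sensor forward-model defaults (baseline_r0 ohm, sensitivity_k per %v/v,
# gamma).  Chosen once for realism: MQ-3 is the most ethanol-sensitive channel
# (its steady-state voltage walks from ~0.75 V at 1 % to ~3 V at 8 %); the two
# channels that proved uninformative on the physical instrument (MQ-135,
# TGS822) are given the weakest response; MQ-9, whose listed target gases do
# not include ethanol, responds weakly through cross-sensitivity.
DEFAULT_RESPONSE: dict[str, tuple[float, float, float]] = {
    "MQ-2": (80_000.0, 0.8, 1.0),
    "MQ-3": (175_000.0, 1.0, 1.5),
    "MQ-4": (60_000.0, 0.6, 0.8),
    "MQ-5": (70_000.0, 0.7, 0.9),
    "MQ-6": (65_000.0, 0.6, 0.85),
    "MQ-7": (50_000.0, 0.5, 0.7),
    "MQ-8": (90_000.0, 0.9, 1.1),
    "MQ-9": (40_000.0, 0.3, 0.5),
    "MQ-135": (30_000.0, 0.15, 0.25),
    "TGS822": (45_000.0, 0.2, 0.3),
    "TGS2600": (85_000.0, 0.8, 1.2),
    "TGS2602": (75_000.0, 0.7, 1.0),
    "TGS2603": (55_000.0, 0.5, 0.75),
}

#: Canonical dataset column order (sensor columns are inserted in registry order).
DATASET_COLUMNS = (
    "time_s",
    "temperature_c",
    "humidity_pct",
    "pressure_hpa",
    "sample_id",
    "measurement_id",
    "label_abv",
)


@dataclass(frozen=True)
class ProtocolDesign:
    """Calibration/test experimental design.

    ``warmup_s`` is the preheating time that elapses before recording starts;
    the emitted series therefore has ``duration_s * rate_hz`` samples carrying
    only the residual tail of the warm-up transient.
    """

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    runs: tuple[tuple[float, float, float], ...] = DEFAULT_RUNS
    duration_s: float = 480.0
    rate_hz: float = 1.0
    warmup_s: float = 600.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ConfigError("duration_s and rate_hz must be positive")
        if self.warmup_s < 0:
            raise ConfigError("warmup_s must be non-negative")
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("concentrations must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


@dataclass(frozen=True)
class BeverageSpec:
    """A simulated commercial beverage.

    ``true_abv`` drives the simulator; ``labeled_abv`` is what the bottle
    claims and what evaluation compares against.  ``voc_multiplier >= 1``
    inflates the effective concentration seen by the sensors to mimic
    beverages that emit extra non-ethanol volatiles.
    """

    name: str
    true_abv: float
    labeled_abv: float
    voc_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.true_abv < 0 or self.labeled_abv < 0:
            raise ConfigError(f"beverage {self.name!r}: negative alcohol content")
        if self.voc_multiplier < 1.0:
            raise ConfigError(f"beverage {self.name!r}: voc_multiplier must be >= 1")

    @property
    def effective_abv(self) -> float:
        """Concentration the sensors respond to."""
        return self.true_abv * self.voc_multiplier


def default_beverages() -> tuple[BeverageSpec, ...]:
    """The seven-beer test panel with labeled contents as ground truth.

    C4M, a dark malt beer with a markedly stronger odor than C4, carries a
    voc_multiplier above 1 so the two nominally-4% beers are distinguishable.
    """
    return (
        BeverageSpec("C4", 4.0, 4.0),
        BeverageSpec("C4M", 4.0, 4.0, voc_multiplier=1.15),
        BeverageSpec("C4.5", 4.5, 4.5),
        BeverageSpec("C4.6", 4.6, 4.6),
        BeverageSpec("C5", 5.0, 5.0),
        BeverageSpec("C5.4", 5.4, 5.4),
        BeverageSpec("C7.9", 7.9, 7.9),
    )


def _default_response_field() -> dict[str, tuple[float, float, float]]:
    return dict(DEFAULT_RESPONSE)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable knobs of the forward model.

    Same seed + same design => bit-identical dataset: every measurement draws
    from its own generator keyed on (seed, stage, measurement index).
    """

    seed: int = 0
    noise_sd: float = 0.06
    noise_model: str = "lognormal"  # or "additive" (Gaussian on voltage)
    tau_s: float = 120.0
    test_condition: tuple[float, float] = (30.0, 41.0)
    test_pressure_hpa: float = 1010.0
    response: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_response_field
    )
    v_cc: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.noise_model not in ("lognormal", "additive"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.tau_s <= 0:
            raise ConfigError("tau_s must be positive")
        for name, (r0, k, gamma) in self.response.items():
            if r0 <= 0 or k <= 0 or gamma <= 0:
                raise ConfigError(
                    f"sensor {name!r}: baseline_r0, sensitivity_k and gamma "
                    "must all be positive"
                )


def true_resistance(conc: float, sensor_name: str, config: SimulationConfig) -> float:
    """Noise- and ambient-free sensor resistance at concentration ``conc``."""
    if conc < 0:
        raise DomainError(f"negative concentration {conc}")
    try:
        r0, k, gamma = config.response[sensor_name]
    except KeyError:
        raise ConfigError(f"no response parameters for sensor {sensor_name!r}") from None
    return r0 * (1.0 + k * conc) ** (-gamma)


def simulate_measurement(
    conc: float,
    condition: tuple[float, float],
    config: SimulationConfig,
    design: ProtocolDesign,
    sensor: SensorSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one channel of one measurement; returns output voltages.

    The observed resistance is
    ``R_true(conc) * D(T, RH) * (1 + exp(-(t + warmup_s)/tau)) * noise`` so
    dividing an observed resistance by the compensation denominator recovers
    the concentration-only response times transient times noise exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(design.n_samples, dtype=float) / design.rate_hz
    temp, rh = condition
    d = compensation_denominator(sensor, temp, rh)
    if d <= 0:
        raise AmbientEnvelopeError(
            f"sensor {sensor.name!r}: simulated conditions ({temp}, {rh}) outside "
            "the calibrated ambient envelope"
        )
    r_true = true_resistance(conc, sensor.name, config)
    transient = 1.0 + np.exp(-(t + design.warmup_s) / config.tau_s)
    r_obs = r_true * d * transient
    if config.noise_model == "lognormal" and config.noise_sd > 0:
        r_obs = r_obs * np.exp(config.noise_sd * rng.standard_normal(t.size))
    v = resistance_to_voltage(r_obs, sensor, config.v_cc)
    if config.noise_model == "additive" and config.noise_sd > 0:
        v = v + config.noise_sd * rng.standard_normal(t.size)
    return np.asarray(v, dtype=float)


def _measurement_frame(
    registry: Mapping[str, SensorSpec],
    conc_effective: float,
    label: float,
    condition: tuple[float, float],
    pressure: float,
    sample_id: str,
    measurement_id: str,
    config: SimulationConfig,
    design: ProtocolDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = design.n_samples
    data: dict[str, np.ndarray] = {"time_s": np.arange(n, dtype=float) / design.rate_hz}
    for name, spec in registry.items():
        data[name] = simulate_measurement(
            conc_effective, condition, config, design, spec, rng=rng
        )
    data["temperature_c"] = np.full(n, condition[0])
    data["humidity_pct"] = np.full(n, condition[1])
    data["pressure_hpa"] = np.full(n, pressure)
    frame = pd.DataFrame(data)
    frame["sample_id"] = sample_id
    frame["measurement_id"] = measurement_id
    frame["label_abv"] = label
    return frame


def simulate_calibration_dataset(
    design: ProtocolDesign | None = None,
    config: SimulationConfig | None = None,
    registry: Mapping[str, SensorSpec] | None = None,
) -> pd.DataFrame:
    """Simulate the full calibration campaign: every run measures every standard.

    Record count is ``len(concentrations) * len(runs) * duration_s * rate_hz``
    (90 measurements x 480 records = 43,200 under the default design).
    """
    design = design or ProtocolDesign()
    config = config or SimulationConfig()
    registry = registry or load_registry()
    if not design.concentrations or not design.runs:
        raise ConfigError("calibration design needs >= 1 concentration and >= 1 run")
    frames = []
    m_index = 0
    for run_idx, (temp, rh, pressure) in enumerate(design.runs):
        for conc in design.concentrations:
            rng = np.random.default_rng([config.seed, 0, m_index])
            frames.append(
                _measurement_frame(
                    registry,
                    conc_effective=conc,
                    label=conc,
                    condition=(temp, rh),
                    pressure=pressure,
                    sample_id=f"cal-{conc:g}",
                    measurement_id=f"cal-r{run_idx}-{conc:g}",
                    config=config,
                    design=design,
                    rng=rng,
                )
            )
            m_index += 1
    return pd.concat(frames, ignore_index=True)


def simulate_test_dataset(
    beers: Sequence[BeverageSpec] | None = None,
    bottles_per_beer: int = 2,
    design: ProtocolDesign | None = None,
    config: SimulationConfig | None = None,
    registry: Mapping[str, SensorSpec] | None = None,
) -> pd.DataFrame:
    """Simulate the commercial-beverage test campaign at the test condition.

    Each beer is measured ``bottles_per_beer`` times (7 x 2 = 14 measurements,
    6,720 records under the defaults).  The concentration the sensors see is
    ``true_abv * voc_multiplier``; the record label is the labeled content.
    """
    beers = default_beverages() if beers is None else tuple(beers)
    design = design or ProtocolDesign()
    config = config or SimulationConfig()
    registry = registry or load_registry()
    if not beers:
        raise ConfigError("empty beverage list")
    if bottles_per_beer < 1:
        raise ConfigError("bottles_per_beer must be >= 1")
    frames = []
    m_index = 0
    for beer in beers:
        for bottle in range(bottles_per_beer):
            rng = np.random.default_rng([config.seed, 1, m_index])
            frames.append(
                _measurement_frame(
                    registry,
                    conc_effective=beer.effective_abv,
                    label=beer.labeled_abv,
                    condition=config.test_condition,
                    pressure=config.test_pressure_hpa,
                    sample_id=beer.name,
                    measurement_id=f"test-{beer.name}-b{bottle}",
                    config=config,
                    design=design,
                    rng=rng,
                )
            )
            m_index += 1
    return pd.concat(frames, ignore_index=True)
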