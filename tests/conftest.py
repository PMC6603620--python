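"""Shared fixtures.

Expensive whole-campaign simulations are session-scoped so the protocol
arithmetic, compensation and recovery checks share one dataset each.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from enose.preprocess import preprocess_pipeline
from enose.sensor_model import load_registry
from enose.synthetic_data import (
    ProtocolDesign,
    SimulationConfig,
    default_beverages,
    simulate_calibration_dataset,
    simulate_test_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_design():
    """Reduced protocol for cheap unit tests: 3 standards, 2 runs, 60 s."""
    return ProtocolDesign(
        concentrations=(1.0, 4.0, 8.0),
        runs=((25.0, 33.0, 1012.0), (27.0, 31.0, 1009.0)),
        duration_s=60.0,
    )


@pytest.fixture(scope="session")
def zero_noise_config():
    return SimulationConfig(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def unit_voc_beverages():
    """The seven-beer panel with every voc_multiplier forced to 1."""
    return tuple(
        dataclasses.replace(b, voc_multiplier=1.0) for b in default_beverages()
    )


@pytest.fixture(scope="session")
def calib_full_zero(registry, zero_noise_config):
    """Full calibration campaign, zero noise (43,200 records)."""
    return simulate_calibration_dataset(
        ProtocolDesign(), zero_noise_config, registry
    )


@pytest.fixture(scope="session")
def calib_full_default(registry, default_config):
    """Full calibration campaign at the default noise level."""
    return simulate_calibration_dataset(ProtocolDesign(), default_config, registry)


@pytest.fixture(scope="session")
def test_full_default(registry, default_config):
    """Full seven-beer test campaign at the default noise level."""
    return simulate_test_dataset(
        default_beverages(), 2, ProtocolDesign(), default_config, registry
    )


@pytest.fixture(scope="session")
def features_full_default(registry, calib_full_default):
    """Preprocessed (normalized) calibration features at default noise."""
    return preprocess_pipeline(calib_full_default, registry)


@pytest.fixture(scope="session")
def small_calibration(registry, small_design, default_config):
    return simulate_calibration_dataset(small_design, default_config, registry)
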