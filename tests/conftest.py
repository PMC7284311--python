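"""Shared fixtures: synthetic sessions reused across test modules."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

from gazekit.synthetic import SimConfig, simulate_sensor_session, simulate_session

# make scripts/acceptance.py importable for the acceptance tests
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))


@pytest.fixture(scope="session")
def session600():
    """Default 600-s freely-moving session."""
    return simulate_session(SimConfig(seed=1))


@pytest.fixture(scope="session")
def session300():
    """Shorter session for mid-weight analyses."""
    return simulate_session(SimConfig(seed=2, duration_s=300.0))


@pytest.fixture(scope="session")
def sensor_session():
    """Head-restrained session with a piezo sensor."""
    return simulate_sensor_session(SimConfig(seed=5, duration_s=300.0))


@pytest.fixture(scope="session")
def noise_sensor_session():
    """Sensor recording without saccades (noise-only reference)."""
    return simulate_sensor_session(
        SimConfig(seed=6, duration_s=60.0, saccade_rate_hz=0.0, attempt_rate_hz=0.0)
    )
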