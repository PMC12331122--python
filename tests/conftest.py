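"""Shared fixtures: small simulated recordings reused across test modules."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from splitvent import (CircuitSpec, LungParams, VentilatorSettings,
                       simulate_setting)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


C_NORMAL = 0.100   # L/cmH2O
C_LOW = 0.020


@pytest.fixture(scope="session")
def lung_normal():
    return LungParams(compliance=C_NORMAL, raw=30.0)


@pytest.fixture(scope="session")
def lung_low():
    return LungParams(compliance=C_LOW, raw=30.0)


@pytest.fixture(scope="session")
def pcv_rr15():
    return VentilatorSettings(mode="PCV", rr=15, pinsp_above_peep=10.0)


@pytest.fixture(scope="session")
def vcv_rr15():
    return VentilatorSettings(mode="VCV", rr=15, vt_set_per_lung=0.450)


@pytest.fixture(scope="session")
def circuit1():
    return CircuitSpec(topology="circuit1")


@pytest.fixture(scope="session")
def pcv_record(pcv_rr15, lung_normal, circuit1):
    """PCV RR 15, C 100/100, circuit-1; 3 min (enough for steady state)."""
    return simulate_setting(pcv_rr15, lung_normal, lung_normal, circuit1,
                            duration=180.0)


@pytest.fixture(scope="session")
def vcv_record(vcv_rr15, lung_normal, circuit1):
    """VCV RR 15 reference cell recording, circuit-1, 3 min."""
    return simulate_setting(vcv_rr15, lung_normal, lung_normal, circuit1,
                            duration=180.0)


@pytest.fixture(scope="session")
def single_branch_pcv():
    """One lung on an ideal pressure step: the RC-oracle configuration.

    Branch 2 is occluded (enormous resistance) and the source impedance and
    node compliance are kept small so the node tracks the set pressure;
    lung 1 then sees a clean first-order RC charge with tau = Raw * C.
    """
    s = VentilatorSettings(mode="PCV", rr=2, insp_frac=0.5, peep=0.0,
                           pinsp_above_peep=10.0, rise_time=0.0)
    l1 = LungParams(compliance=C_NORMAL, raw=30.0)
    l2 = LungParams(compliance=0.001, raw=1e7)
    c = CircuitSpec(topology="circuit1", tube_resistance_per_limb=0.0,
                    circuit_compliance=1e-3, vent_resistance=1e-2)
    return simulate_setting(s, l1, l2, c, duration=60.0)
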