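"""Lumped-parameter model of one ventilator ventilating two passive lungs.

The bench being emulated: an ICU ventilator drives two single-compartment
test lungs through individual 3 m / 22 mm tubing limbs, either as a plain
split (circuit-1) or with one-way valves plus an adjustable orifice
resistance valve in front of lung 2 (circuit-2).  Each lung obeys the
single-compartment equation of motion

    P_aw = V / C + Raw * V' + PEEP

and the two branches couple at a common wye node carrying an effective
circuit (tubing/compressible-gas) compliance.  The ventilator is a
pressure source with a linear rise ramp (PCV) or a constant-flow source
over the inspiratory fraction with a hard pressure cap (VCV).

Units: pressures cmH2O, flows L/s, volumes L, resistances cmH2O.s/L,
compliances L/cmH2O, times s.  Flow at a lung port is inspiratory-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._engine import MODE_PCV, MODE_VCV, TOPO_C1, TOPO_C2, integrate

CMH2O_PER_MBAR = 1.0197
#: ventilator working-pressure ceiling of 40 mbar, above which a valve
#: setting/flow combination could not be characterised on the bench
VALVE_FEASIBLE_MAX_CMH2O = 40.0 * CMH2O_PER_MBAR

#: Effective circuit compliance at the common node [L/cmH2O], calibrated so
#: that the ventilator-vs-lungs volume discrepancy at the circuit-1 VCV
#: reference cell (450 ml/lung, RR 15, C 100/100) reproduces the ~200 ml
#: loss reported for the bench.  See docs/methods.md.
DEFAULT_CIRCUIT_COMPLIANCE = 9.2e-3

#: Orifice coefficients k_s [cmH2O.s^2/L^2] for valve settings 1..6,
#: geometrically spaced; k_6 calibrated so that fully closing the valve
#: diverts ~100 ml away from lung 2 at the reference cell (PCV, RR 15,
#: C 100/100).  See docs/methods.md.
DEFAULT_VALVE_K = (2.0, 7.04, 24.8, 87.2, 307.0, 1081.0)


class ConfigError(ValueError):
    """Raised for invalid ventilator / lung / circuit configuration."""


@dataclass(frozen=True)
class VentilatorSettings:
    """Mandatory-mode ventilator settings.

    ``insp_frac`` is the inspiratory fraction of the cycle: an I:E ratio of
    1:5 corresponds to ``insp_frac = 1/6``.
    """

    mode: str                       # "PCV" | "VCV"
    rr: float                       # breaths/min
    insp_frac: float = 1.0 / 6.0
    peep: float = 8.0               # cmH2O
    pinsp_above_peep: Optional[float] = None   # cmH2O (PCV)
    vt_set_per_lung: Optional[float] = None    # L (VCV)
    p_max: float = 35.0             # cmH2O inspiratory pressure cap
    rise_time: float = 0.1          # s, inspiratory pressurisation/flow ramp
    release_time: float = 0.05      # s, exhalation-valve pressure release

    def __post_init__(self) -> None:
        if self.mode not in ("PCV", "VCV"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not (1 <= self.rr <= 60):
            raise ConfigError(f"rr out of range: {self.rr}")
        if not (0.0 < self.insp_frac < 1.0):
            raise ConfigError(f"insp_frac out of range: {self.insp_frac}")
        if self.peep < 0:
            raise ConfigError("peep must be >= 0")
        if self.p_max <= self.peep:
            raise ConfigError("p_max must exceed peep")
        if self.mode == "PCV":
            if self.pinsp_above_peep is None or self.vt_set_per_lung is not None:
                raise ConfigError("PCV requires pinsp_above_peep only")
            if self.pinsp_above_peep <= 0:
                raise ConfigError("pinsp_above_peep must be > 0")
        else:
            if self.vt_set_per_lung is None or self.pinsp_above_peep is not None:
                raise ConfigError("VCV requires vt_set_per_lung only")
            if self.vt_set_per_lung <= 0:
                raise ConfigError("vt_set_per_lung must be > 0")

    @property
    def ie_ratio(self) -> float:
        """I:E expressed as a single number I/E (1:5 -> 0.2)."""
        return self.insp_frac / (1.0 - self.insp_frac)

    @property
    def t_cycle(self) -> float:
        return 60.0 / self.rr

    @property
    def t_insp(self) -> float:
        return self.t_cycle * self.insp_frac


@dataclass(frozen=True)
class LungParams:
    """Single-compartment passive lung."""

    compliance: float   # L/cmH2O
    raw: float = 30.0   # cmH2O.s/L, linear airway resistance

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ConfigError("compliance must be > 0")
        if self.raw < 0:
            raise ConfigError("raw must be >= 0")

    def volume_offset(self, peep: float) -> float:
        """Volume above FRC stored at the PEEP-equilibrated baseline [L]."""
        return self.compliance * peep


class OrificeValveModel:
    """Adjustable resistance valve as a family of orifice laws.

    Setting ``s`` (1 = fully open .. 6 = most closed) maps to
    ``dP = k_s * Q**2`` with ``k_s`` non-decreasing in ``s``.
    """

    def __init__(self, k: Sequence[float] = DEFAULT_VALVE_K):
        k = tuple(float(v) for v in k)
        if len(k) != 6 or any(v < 0 for v in k):
            raise ConfigError("need 6 non-negative orifice coefficients")
        if any(b < a for a, b in zip(k, k[1:])):
            raise ConfigError("orifice coefficients must be non-decreasing")
        self.k = k

    def coefficient(self, setting: int) -> float:
        _check_setting(setting)
        return self.k[setting - 1]

    def pressure_drop(self, setting: int, flow_lps: float) -> float:
        if flow_lps < 0:
            raise ValueError("flow must be >= 0")
        return self.coefficient(setting) * flow_lps ** 2


class TableValveModel:
    """Valve characterised by a (setting, flow, pressure-drop) table.

    Interpolates linearly in Q**2 between tabulated flows, which is exact
    for an orifice and extrapolates through the origin below the smallest
    tabulated flow.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"setting", "flow_lpm", "dp_cmh2o"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"valve table missing columns: {sorted(missing)}")
        self.table = table.sort_values(["setting", "flow_lpm"]).reset_index(drop=True)

    def pressure_drop(self, setting: int, flow_lps: float) -> float:
        if flow_lps < 0:
            raise ValueError("flow must be >= 0")
        _check_setting(setting)
        sub = self.table[self.table["setting"] == setting]
        if sub.empty:
            raise ConfigError(f"no table rows for valve setting {setting}")
        q2 = (sub["flow_lpm"].to_numpy() / 60.0) ** 2
        dp = sub["dp_cmh2o"].to_numpy()
        x = flow_lps ** 2
        # linear in Q^2, anchored at the origin
        return float(np.interp(x, np.concatenate(([0.0], q2)),
                               np.concatenate(([0.0], dp))))

    def coefficient(self, setting: int) -> float:
        """Least-squares orifice coefficient for one setting (dp ~ k Q^2)."""
        sub = self.table[self.table["setting"] == setting]
        q2 = (sub["flow_lpm"].to_numpy() / 60.0) ** 2
        dp = sub["dp_cmh2o"].to_numpy()
        denom = float(np.dot(q2, q2))
        if denom == 0.0:
            raise ConfigError(f"degenerate valve table for setting {setting}")
        return float(np.dot(q2, dp) / denom)


def _check_setting(setting: int) -> None:
    if not (isinstance(setting, (int, np.integer)) and 1 <= setting <= 6):
        raise ValueError(f"valve setting must be an integer in 1..6, got {setting!r}")


@dataclass(frozen=True)
class CircuitSpec:
    """Topology and passive properties of the shared breathing circuit."""

    topology: str                               # "circuit1" | "circuit2"
    tube_resistance_per_limb: float = 2.0       # cmH2O.s/L per 3 m limb
    circuit_compliance: float = DEFAULT_CIRCUIT_COMPLIANCE  # L/cmH2O
    valve_setting: Optional[int] = None         # circuit-2 only
    valve_model: Optional[object] = None        # OrificeValveModel | TableValveModel
    oneway_forward_resistance: float = 0.5      # cmH2O.s/L
    vent_resistance: float = 0.5                # machine source impedance

    def __post_init__(self) -> None:
        if self.topology not in ("circuit1", "circuit2"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.topology == "circuit1" and self.valve_setting is not None:
            raise ConfigError("valve_setting is only valid on circuit-2")
        if self.topology == "circuit2" and self.valve_setting is None:
            raise ConfigError("circuit-2 requires a valve_setting (1..6)")
        if self.valve_setting is not None:
            _check_setting(self.valve_setting)
        for name in ("tube_resistance_per_limb", "oneway_forward_resistance"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.circuit_compliance <= 0:
            raise ConfigError("circuit_compliance must be > 0 (lumped node)")
        if self.vent_resistance <= 0:
            raise ConfigError("vent_resistance must be > 0")
        if self.topology == "circuit2" and self.valve_model is None:
            object.__setattr__(self, "valve_model", OrificeValveModel())


@dataclass
class WaveformRecord:
    """Synchronised multi-channel recording of one simulated setting.

    ``channels`` columns: t_s, p_vent, q_vent, p_sim1, q_sim1, p_sim2,
    q_sim2 plus cumulative volumes v_vent, v_sim1, v_sim2 (L, integrated at
    the internal step).  Flow at each lung port is inspiratory-positive and
    cumulative volumes start at 0 above the PEEP-equilibrated baseline.
    """

    sample_rate: float
    channels: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def duration(self) -> float:
        t = self.channels["t_s"].to_numpy()
        return float(t[-1] - t[0]) + 1.0 / self.sample_rate

    def __len__(self) -> int:
        return len(self.channels)


def simulate_setting(settings: VentilatorSettings,
                     lung1: LungParams,
                     lung2: LungParams,
                     circuit: CircuitSpec,
                     duration: float = 360.0,
                     noise_sd: Tuple[float, float] = (0.0, 0.0),
                     seed: int = 0,
                     sample_rate: float = 100.0,
                     internal_step: float = 1e-3) -> WaveformRecord:
    """Forward-simulate one experimental setting.

    ``noise_sd`` is (pressure sd cmH2O, flow sd L/s) of additive Gaussian
    sensor noise applied to the pressure/flow channels; the cumulative
    volume channels remain integrals of the noise-free flows.  With
    ``noise_sd == (0, 0)`` the output is deterministic for fixed inputs.
    """
    if duration < 2.0 * settings.t_cycle:
        raise ConfigError(
            f"duration {duration} s is shorter than two breath periods "
            f"({2 * settings.t_cycle:.1f} s)")
    if internal_step > 2e-3:
        raise ConfigError("internal integration step must be <= 2 ms")

    dt_out = 1.0 / sample_rate
    n_samples = int(round(duration * sample_rate))

    topo = TOPO_C1 if circuit.topology == "circuit1" else TOPO_C2
    mode = MODE_PCV if settings.mode == "PCV" else MODE_VCV
    oneway = circuit.oneway_forward_resistance if topo == TOPO_C2 else 0.0
    r1 = circuit.tube_resistance_per_limb + oneway + lung1.raw
    r2 = circuit.tube_resistance_per_limb + oneway + lung2.raw
    k2 = 0.0
    if topo == TOPO_C2:
        k2 = circuit.valve_model.coefficient(circuit.valve_setting)
    r_exp1 = circuit.tube_resistance_per_limb + oneway + lung1.raw
    r_exp2 = circuit.tube_resistance_per_limb + oneway + lung2.raw

    dp_insp = settings.pinsp_above_peep or 0.0
    q_set = 0.0
    if settings.mode == "VCV":
        # plateau flow compensated for the linear rise ramp so the
        # commanded inspiratory volume is 2 x vt_set_per_lung
        if settings.rise_time >= settings.t_insp:
            raise ConfigError("rise_time must be shorter than the "
                              "inspiratory time")
        q_set = (2.0 * settings.vt_set_per_lung
                 / (settings.t_insp - 0.5 * settings.rise_time))

    # the node is the fastest pole: keep the explicit step well inside its
    # time constant so small circuit compliances stay stable
    g_node = 1.0 / circuit.vent_resistance + 1.0 / r1 + 1.0 / r2
    tau_node = circuit.circuit_compliance / g_node
    h_eff = min(internal_step, 0.5 * tau_node)
    n_sub = max(1, math.ceil(dt_out / h_eff))
    if n_sub > 50000:
        raise ConfigError(
            "circuit configuration is too stiff for the fixed-step "
            "integrator (node time constant below 0.4 us)")

    out = integrate(n_samples, dt_out, n_sub, mode, float(settings.rr),
                    float(settings.insp_frac), float(settings.peep),
                    float(dp_insp), float(settings.rise_time),
                    float(settings.release_time), float(q_set),
                    float(settings.p_max), float(lung1.compliance),
                    float(lung2.compliance), float(lung1.raw),
                    float(lung2.raw), float(r1), float(r2), float(k2),
                    float(r_exp1), float(r_exp2),
                    float(circuit.circuit_compliance),
                    float(circuit.vent_resistance), topo)
    (p_vent, q_vent, p_sim1, q_sim1, p_sim2, q_sim2,
     v_vent, v_sim1, v_sim2, capped) = out

    t = np.arange(n_samples) * dt_out
    df = pd.DataFrame({
        "t_s": t, "p_vent": p_vent, "q_vent": q_vent,
        "p_sim1": p_sim1, "q_sim1": q_sim1,
        "p_sim2": p_sim2, "q_sim2": q_sim2,
        "v_vent": v_vent, "v_sim1": v_sim1, "v_sim2": v_sim2,
    })
    p_sd, q_sd = noise_sd
    if p_sd > 0 or q_sd > 0:
        rng = np.random.default_rng(seed)
        for col in ("p_vent", "p_sim1", "p_sim2"):
            df[col] += rng.normal(0.0, p_sd, n_samples)
        for col in ("q_vent", "q_sim1", "q_sim2"):
            df[col] += rng.normal(0.0, q_sd, n_samples)

    meta = {
        "settings": {
            "mode": settings.mode, "rr": settings.rr,
            "insp_frac": settings.insp_frac, "peep": settings.peep,
            "pinsp_above_peep": settings.pinsp_above_peep,
            "vt_set_per_lung": settings.vt_set_per_lung,
            "p_max": settings.p_max, "rise_time": settings.rise_time,
            "release_time": settings.release_time,
        },
        "lung1": {"compliance": lung1.compliance, "raw": lung1.raw},
        "lung2": {"compliance": lung2.compliance, "raw": lung2.raw},
        "circuit": {
            "topology": circuit.topology,
            "tube_resistance_per_limb": circuit.tube_resistance_per_limb,
            "circuit_compliance": circuit.circuit_compliance,
            "valve_setting": circuit.valve_setting,
            "oneway_forward_resistance": circuit.oneway_forward_resistance,
            "vent_resistance": circuit.vent_resistance,
        },
        "duration": duration, "sample_rate": sample_rate,
        "noise_sd": list(noise_sd), "seed": seed,
        "internal_step": dt_out / n_sub,
        "cap_limited": bool(capped),
    }
    return WaveformRecord(sample_rate=sample_rate, channels=df,
                          metadata=meta, seed=seed)


# ---------------------------------------------------------------------------
# valve operations

def valve_pressure_drop(model, setting: int, flow_lpm: float
                        ) -> Tuple[float, bool]:
    """Pressure drop [cmH2O] across the valve and bench feasibility.

    ``flow_lpm`` is in L/min as in the characterisation protocol.  A
    combination is infeasible when the drop exceeds the ventilator's 40 mbar
    working-pressure ceiling, in which case it could not be assessed.
    """
    if flow_lpm < 0:
        raise ValueError("flow must be >= 0")
    _check_setting(setting)
    dp = model.pressure_drop(setting, flow_lpm / 60.0)
    return dp, dp <= VALVE_FEASIBLE_MAX_CMH2O


def characterize_valve(model, flows_lpm: Sequence[float],
                       settings: Sequence[int] = range(1, 7)) -> pd.DataFrame:
    """Sweep the valve over settings x flows.

    Returns one row per (setting, flow) with the pressure drop, the
    equivalent resistance dP/Q [cmH2O.s/L] and the feasibility flag.
    """
    flows = list(flows_lpm)
    if not flows:
        raise ValueError("flow list must be non-empty")
    if any(f <= 0 for f in flows):
        raise ValueError("characterisation flows must be positive")
    rows = []
    for s in settings:
        for f in flows:
            dp, feasible = valve_pressure_drop(model, s, f)
            rows.append({
                "setting": int(s), "flow_lpm": float(f), "dp_cmh2o": dp,
                "resistance_cmh2o_s_l": dp / (f / 60.0),
                "feasible": feasible,
            })
    return pd.DataFrame(rows)


def fit_orifice_coefficients(table: pd.DataFrame) -> pd.Series:
    """Least-squares orifice coefficients k_s from a characterisation table.

    Fits dp = k * Q^2 per setting over the feasible rows; the independent
    check for the table-based valve model.
    """
    tv = TableValveModel(table)
    settings = sorted(table["setting"].unique())
    return pd.Series({int(s): tv.coefficient(int(s)) for s in settings},
                     name="k_cmh2o_s2_l2")
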