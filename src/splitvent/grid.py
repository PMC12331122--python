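"""Protocol runner: the full study grid, paired statistics, diversion.

The protocol crosses circuit {1, 2} x mode {PCV, VCV} x RR {15, 30} x
compliance pairs {(100,100), (100,20), (20,20)} ml/cmH2O, and for
circuit-2 additionally the six settings of the adjustable resistance
valve: 12 cells for circuit-1 and 72 for circuit-2.  Every cell is
simulated, pushed through the waveform pipeline and summarised per lung
simulator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import pipeline
from .power import mp_gattinoni
from .simulator import (CircuitSpec, ConfigError, LungParams,
                        VentilatorSettings, simulate_setting)

DEFAULT_COMPLIANCE_PAIRS_ML = ((100, 100), (100, 20), (20, 20))
DEFAULT_PINSP_ABOVE_PEEP = 10.0     # cmH2O
DEFAULT_VT_SET_PER_LUNG = 0.450     # L
DEFAULT_RAW = 30.0                  # cmH2O.s/L


@dataclass(frozen=True)
class ProtocolGrid:
    """The study grid for one circuit."""

    circuit: int                                   # 1 | 2
    modes: Tuple[str, ...] = ("PCV", "VCV")
    rrs: Tuple[float, ...] = (15.0, 30.0)
    compliance_pairs_ml: Tuple[Tuple[float, float], ...] = \
        DEFAULT_COMPLIANCE_PAIRS_ML
    valve_settings: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    duration: float = 360.0
    discard: float = 60.0
    base_seed: int = 0
    noise_sd: Tuple[float, float] = (0.0, 0.0)
    raw: float = DEFAULT_RAW
    pinsp_above_peep: float = DEFAULT_PINSP_ABOVE_PEEP
    vt_set_per_lung: float = DEFAULT_VT_SET_PER_LUNG
    circuit_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.circuit not in (1, 2):
            raise ConfigError("circuit must be 1 or 2")
        if self.duration <= self.discard:
            raise ConfigError("duration must exceed the discard window")

    def cells(self) -> Iterator[dict]:
        valves: Sequence[Optional[int]]
        valves = self.valve_settings if self.circuit == 2 else (None,)
        for mode in self.modes:
            for rr in self.rrs:
                for c1, c2 in self.compliance_pairs_ml:
                    for v in valves:
                        label = (f"c{self.circuit}-{mode}-rr{int(rr)}"
                                 f"-C{int(c1)}/{int(c2)}-v{v or 0}")
                        yield {"label": label, "mode": mode, "rr": rr,
                               "c1_ml": c1, "c2_ml": c2,
                               "valve_setting": v,
                               "seed": cell_seed(self.base_seed, label)}

    @property
    def n_cells(self) -> int:
        n = len(self.modes) * len(self.rrs) * len(self.compliance_pairs_ml)
        return n * (len(self.valve_settings) if self.circuit == 2 else 1)


def cell_seed(base_seed: int, label: str) -> int:
    """Reproducible, distinct per-cell seed (stable across processes)."""
    return (int(base_seed) * 1000003 + zlib.crc32(label.encode())) % (2**31 - 1)


def _cell_objects(grid: ProtocolGrid, cell: dict):
    mode = cell["mode"]
    if mode == "PCV":
        settings = VentilatorSettings(
            mode="PCV", rr=cell["rr"],
            pinsp_above_peep=grid.pinsp_above_peep)
    else:
        settings = VentilatorSettings(
            mode="VCV", rr=cell["rr"],
            vt_set_per_lung=grid.vt_set_per_lung)
    lung1 = LungParams(compliance=cell["c1_ml"] / 1000.0, raw=grid.raw)
    lung2 = LungParams(compliance=cell["c2_ml"] / 1000.0, raw=grid.raw)
    circuit = CircuitSpec(
        topology=f"circuit{grid.circuit}",
        valve_setting=cell["valve_setting"],
        **grid.circuit_overrides)
    return settings, lung1, lung2, circuit


def run_cell(grid: ProtocolGrid, cell: dict,
             channels: Sequence[str] = ("sim1", "sim2")) -> list[dict]:
    """Simulate and summarise one grid cell; one output row per channel."""
    settings, lung1, lung2, circuit = _cell_objects(grid, cell)
    record = simulate_setting(settings, lung1, lung2, circuit,
                              duration=grid.duration,
                              noise_sd=grid.noise_sd, seed=cell["seed"])
    summary, per_channel = pipeline.analyze_record(
        record, rr=cell["rr"], channels=channels, discard=grid.discard)
    lungs = {"sim1": lung1, "sim2": lung2}
    rows = []
    for ch in channels:
        s = summary.table.loc[ch]
        row = {**{k: cell[k] for k in ("label", "mode", "rr", "c1_ml",
                                       "c2_ml", "valve_setting", "seed")},
               "channel": ch, "n_breaths": summary.n_breaths[ch],
               "vt_ml_mean": s["vt_mean"] * 1000.0,
               "vt_ml_sd": s["vt_sd"] * 1000.0,
               "p_peak_mean": s["p_peak_mean"], "p_peak_sd": s["p_peak_sd"],
               "p_mean_mean": s["p_mean_mean"], "p_mean_sd": s["p_mean_sd"],
               "mp_mean": s["mp_mean"], "mp_sd": s["mp_sd"],
               "cap_limited": record.metadata["cap_limited"],
               "flag": ""}
        if ch in lungs:
            # closed-form power on the per-breath measured tidal volumes
            lp = lungs[ch]
            mps = [mp_gattinoni(rr=cell["rr"], dv=m.vt,
                                elastance=1.0 / lp.compliance, raw=lp.raw,
                                ie=settings.ie_ratio, peep=settings.peep)
                   for m in per_channel[ch]]
            row["mp_formula_mean"] = float(np.mean(mps))
            row["mp_formula_sd"] = float(np.std(mps, ddof=1))
        else:
            row["mp_formula_mean"] = np.nan
            row["mp_formula_sd"] = np.nan
        rows.append(row)
    return rows


def run_grid(grid: ProtocolGrid,
             channels: Sequence[str] = ("sim1", "sim2")) -> pd.DataFrame:
    """Run every cell of the protocol grid.

    Deterministic for a fixed grid and base seed.  A cell whose
    configuration is infeasible yields a flagged row instead of aborting.
    """
    rows = []
    for cell in grid.cells():
        try:
            rows.extend(run_cell(grid, cell, channels=channels))
        except ConfigError as exc:
            row = {k: cell.get(k) for k in ("label", "mode", "rr", "c1_ml",
                                            "c2_ml", "valve_setting",
                                            "seed")}
            row.update({"channel": "", "flag": f"error: {exc}"})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedDiffResult:
    """Intercept of the paired-difference-vs-time linear model."""

    estimate: float
    ci95: Tuple[float, float]
    p: float
    n: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.estimate <= hi):
            raise ValueError("ci95 must contain the estimate")


def paired_difference(metric1: Sequence[float], metric2: Sequence[float],
                      breath_index: Optional[Sequence[float]] = None
                      ) -> PairedDiffResult:
    """Paired difference (metric2 - metric1) with a breath-index time effect.

    Fits d_i = b0 + b1 * t_i by OLS to account for repeated measurements
    and reports the intercept b0 with its 95% CI and p-value.  The time
    covariate defaults to the breath index 0..n-1, so the estimate is the
    difference at the start of the series, not the raw mean when a drift
    is present.
    """
    m1 = np.asarray(metric1, dtype=float)
    m2 = np.asarray(metric2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("metric series must have equal length")
    n = m1.size
    if n < 3:
        raise ValueError("need at least 3 paired breaths")
    t = (np.arange(n, dtype=float) if breath_index is None
         else np.asarray(breath_index, dtype=float))
    d = m2 - m1
    if np.ptp(d) == 0.0:
        # constant difference: the model is exact, CI degenerates
        est = float(d[0])
        return PairedDiffResult(estimate=est, ci95=(est, est),
                                p=1.0 if est == 0.0 else 0.0, n=n)
    x = sm.add_constant(t)
    fit = sm.OLS(d, x).fit()
    ci = fit.conf_int(alpha=0.05)[0]
    return PairedDiffResult(estimate=float(fit.params[0]),
                            ci95=(float(ci[0]), float(ci[1])),
                            p=float(fit.pvalues[0]), n=n)


def diversion_curve(results: pd.DataFrame) -> pd.DataFrame:
    """Volume-diversion table for one circuit-2 cell family.

    ``results`` must hold run_grid rows (channels sim1, sim2 and vent) for
    a single (mode, rr, compliance) family across all six valve settings.
    Returns one row per setting with the lung and ventilator tidal volumes
    and the cumulative volume diverted away from lung 2 relative to the
    fully open valve.
    """
    need = {1, 2, 3, 4, 5, 6}
    have = set(results["valve_setting"].dropna().astype(int))
    if have != need:
        raise ValueError(f"family must cover valve settings 1..6, got "
                         f"{sorted(have)}")
    if results[["mode", "rr", "c1_ml", "c2_ml"]].drop_duplicates().shape[0] != 1:
        raise ValueError("family must hold a single (mode, rr, compliance) cell")
    rows = []
    for s in sorted(need):
        sub = results[results["valve_setting"] == s].set_index("channel")
        rows.append({
            "valve_setting": s,
            "vt1_ml": float(sub.loc["sim1", "vt_ml_mean"]),
            "vt2_ml": float(sub.loc["sim2", "vt_ml_mean"]),
            "vt_vent_ml": (float(sub.loc["vent", "vt_ml_mean"])
                           if "vent" in sub.index else np.nan),
            "cap_limited": bool(sub["cap_limited"].any()),
        })
    out = pd.DataFrame(rows)
    out["dvt2_ml"] = out["vt2_ml"].iloc[0] - out["vt2_ml"]
    return out


def run_diversion_family(mode: str = "PCV", rr: float = 15.0,
                         c1_ml: float = 100.0, c2_ml: float = 100.0,
                         duration: float = 360.0, discard: float = 60.0,
                         base_seed: int = 0,
                         circuit_overrides: Optional[dict] = None
                         ) -> pd.DataFrame:
    """Convenience: simulate one valve family and return its diversion curve.

    The defaults are the reference cell (PCV, RR 15, C 100/100)."""
    grid = ProtocolGrid(circuit=2, modes=(mode,), rrs=(rr,),
                        compliance_pairs_ml=((c1_ml, c2_ml),),
                        duration=duration, discard=discard,
                        base_seed=base_seed,
                        circuit_overrides=circuit_overrides or {})
    results = run_grid(grid, channels=("vent", "sim1", "sim2"))
    return diversion_curve(results)
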