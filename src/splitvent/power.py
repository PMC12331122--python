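"""Mechanical power of ventilation: closed form, PV-loop form, thresholds.

The closed form is the comprehensive power equation for passive
volume-controlled ventilation,

    MP [J/min] = 0.098 * RR * { dV^2 * [ E_rs / 2
                                + RR * (1 + I:E) / (60 * I:E) * Raw ]
                                + dV * PEEP }

with dV in L, E_rs = 1/C in cmH2O/L, Raw in cmH2O.s/L, PEEP in cmH2O and
I:E the inspiratory:expiratory ratio as a single number (1:5 -> 0.2).
0.098 J per L.cmH2O converts the pressure-volume product to energy.  The
resistive factor RR*(1+I:E)/(60*I:E) is exactly 1/T_insp, so for an ideal
constant-flow breath the closed form equals the inspiratory PV-loop
integral computed by :func:`mp_from_loop`.

A power above 12 J/min is treated as carrying a high probability of
ventilation-induced lung injury under prolonged ventilation; 17 and 22
J/min are the more liberal thresholds in circulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

J_PER_L_CMH2O = 0.098
VILI_THRESHOLD_J_MIN = 12.0

#: defaults applied to literature rows that do not report the quantity;
#: such rows are flagged and excluded from strict checks
DEFAULT_LIT_RAW = 10.0
DEFAULT_LIT_IE = 0.5


@dataclass(frozen=True)
class MPInputs:
    """Arguments of the closed-form power equation."""

    rr: float           # breaths/min
    dv: float           # L
    elastance: float    # cmH2O/L
    raw: float          # cmH2O.s/L
    ie: float           # I:E as a number, 1:5 -> 0.2
    peep: float         # cmH2O


@dataclass(frozen=True)
class MPResult:
    mp: float
    threshold: float
    injurious: bool


def mp_gattinoni(x: Optional[MPInputs] = None, *, rr: float = None,
                 dv: float = None, elastance: float = None,
                 raw: float = None, ie: float = None,
                 peep: float = None) -> float:
    """Closed-form mechanical power [J/min]."""
    if x is not None:
        rr, dv, elastance, raw, ie, peep = (x.rr, x.dv, x.elastance,
                                            x.raw, x.ie, x.peep)
    if ie is None or ie <= 0:
        raise ValueError("I:E must be > 0")
    if min(rr, dv, elastance, raw, peep) < 0:
        raise ValueError("power inputs must be non-negative")
    resistive = rr * (1.0 + ie) / (60.0 * ie) * raw
    return J_PER_L_CMH2O * rr * (dv * dv * (0.5 * elastance + resistive)
                                 + dv * peep)


def mp_from_loop(pressure: np.ndarray, flow: np.ndarray, time: np.ndarray,
                 rr: float) -> float:
    """Mechanical power from the inspiratory PV loop [J/min].

    ``pressure``/``flow``/``time`` cover the inspiratory phase of one
    breath (airway pressure cmH2O, flow L/s).  The inspiratory energy is
    the integral of P dV = P * q dt, converted to J and scaled by the
    breathing rate.
    """
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    time = np.asarray(time, dtype=float)
    if pressure.shape != flow.shape or pressure.shape != time.shape:
        raise ValueError("pressure, flow and time must have equal length")
    if pressure.size < 2:
        raise ValueError("degenerate segment")
    energy = np.trapezoid(pressure * flow, time)   # cmH2O.L
    return float(J_PER_L_CMH2O * rr * energy)


def classify_mp(mp: float, threshold: float = VILI_THRESHOLD_J_MIN
                ) -> MPResult:
    """Injury classification: injurious strictly above the threshold."""
    if mp < 0:
        raise ValueError("mp must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return MPResult(mp=mp, threshold=threshold, injurious=mp > threshold)


# ---------------------------------------------------------------------------
# literature survey

#: canonical columns of a literature settings table
LIT_COLUMNS = ["study", "category", "mode", "vt_ml", "rr", "peep",
               "ie_i", "ie_e", "ppeak", "pplat", "compliance_ml_cmH2O",
               "raw_cmH2O_s_L"]
CATEGORIES = ("human", "animal", "simulator")


def literature_mp_table(table: pd.DataFrame) -> pd.DataFrame:
    """Closed-form MP for every settings row of a literature table.

    Rows missing Raw or I:E receive the survey defaults and are flagged in
    the ``imputed`` column.
    """
    missing = set(LIT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"literature table missing columns: {sorted(missing)}")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    out = table.copy()
    raw = out["raw_cmH2O_s_L"].astype(float)
    ie = out["ie_i"].astype(float) / out["ie_e"].astype(float)
    imputed = raw.isna() | ie.isna()
    raw = raw.fillna(DEFAULT_LIT_RAW)
    ie = ie.fillna(DEFAULT_LIT_IE)
    elastance = 1000.0 / out["compliance_ml_cmH2O"].astype(float)
    mp = [
        mp_gattinoni(rr=r.rr, dv=r.vt_ml / 1000.0, elastance=e,
                     raw=rw, ie=i, peep=r.peep)
        for r, e, rw, i in zip(out.itertuples(), elastance, raw, ie)
    ]
    out["mp_j_min"] = mp
    out["imputed"] = imputed
    out["injurious"] = out["mp_j_min"] > VILI_THRESHOLD_J_MIN
    return out


def literature_aggregate(table: pd.DataFrame,
                         include_imputed: bool = True) -> dict:
    """Per-category MP summary plus the in-vivo vs simulator comparison.

    Pools the per-settings-row closed-form MP within each category (each
    reported setting counts once) and compares the pooled human+animal
    rows against the simulator rows with a two-sample Welch test.
    """
    mp = literature_mp_table(table)
    if not include_imputed:
        mp = mp[~mp["imputed"]]
    rows = []
    for cat in CATEGORIES:
        sub = mp[mp["category"] == cat]
        if sub.empty:
            raise ValueError(f"no rows in category {cat!r}")
        vals = sub["mp_j_min"].to_numpy()
        rows.append({
            "category": cat,
            "n_settings": len(vals),
            "n_studies": sub["study"].nunique(),
            "mp_mean": float(np.mean(vals)),
            "mp_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "sd_defined": len(vals) > 1,
        })
    summary = pd.DataFrame(rows).set_index("category")
    invivo = mp[mp["category"].isin(("human", "animal"))]["mp_j_min"]
    sim = mp[mp["category"] == "simulator"]["mp_j_min"]
    welch = stats.ttest_ind(invivo, sim, equal_var=False)
    return {
        "summary": summary,
        "per_row": mp,
        "comparison": {
            "test": "welch_two_sample_t",
            "statistic": float(welch.statistic),
            "p_value": float(welch.pvalue),
            "invivo_mean": float(invivo.mean()),
            "simulator_mean": float(sim.mean()),
        },
    }


def _invert_vt(mp: float, rr: float, elastance: float, raw: float,
               ie: float, peep: float) -> float:
    """Tidal volume [L] that yields ``mp`` in the closed form (quadratic)."""
    a = 0.5 * elastance + rr * (1.0 + ie) / (60.0 * ie) * raw
    k = mp / (J_PER_L_CMH2O * rr)
    return (-peep + np.sqrt(peep * peep + 4.0 * a * k)) / (2.0 * a)


def synthetic_literature_table() -> pd.DataFrame:
    """Synthetic stand-in for the shared-ventilation literature table.

    The published supplement is not machine-readable, so this table is
    constructed: each study row carries plausible ventilator settings for
    its category, with tidal volumes chosen so that the row-wise
    closed-form powers pool to the reported category summaries (human
    34.98 +- 12.71 over 6 settings rows, animal 24.29 +- 4.22 over 4,
    simulator 8.78 +- 4.80 over 7).  It exercises the survey computation;
    it is not the original data.
    """
    # (study, category, mode, target_mp, rr, peep, ie_i, ie_e, C_ml, raw)
    spec_rows = [
        ("human_a", "human", "PCV", 17.98, 20, 10, 1, 2, 35, 12.0),
        ("human_a", "human", "PCV", 29.14, 22, 12, 1, 2, 35, 12.0),
        ("human_a", "human", "PCV", 43.98, 25, 14, 1, 1.5, 30, 12.0),
        ("human_b", "human", "VCV", 25.98, 20, 10, 1, 2, 40, 10.0),
        ("human_b", "human", "VCV", 40.82, 24, 12, 1, 2, 35, 10.0),
        ("human_b", "human", "VCV", 51.98, 26, 15, 1, 1.5, 30, 10.0),
        ("animal_a", "animal", "VCV", 19.69, 20, 8, 1, 2, 30, 14.0),
        ("animal_a", "animal", "VCV", 21.92, 20, 10, 1, 2, 30, 14.0),
        ("animal_a", "animal", "VCV", 26.66, 24, 10, 1, 2, 28, 14.0),
        ("animal_a", "animal", "VCV", 28.89, 24, 12, 1, 1.5, 28, 14.0),
        ("sim_a", "simulator", "PCV", 2.114, 10, 5, 1, 2, 50, 8.0),
        ("sim_b", "simulator", "PCV", 4.336, 12, 5, 1, 2, 50, 8.0),
        ("sim_c", "simulator", "VCV", 6.558, 12, 6, 1, 2, 45, 10.0),
        ("sim_d", "simulator", "VCV", 8.780, 14, 8, 1, 2, 40, 10.0),
        ("sim_e", "simulator", "PCV", 11.002, 15, 8, 1, 2, 40, 10.0),
        ("sim_f", "simulator", "VCV", 13.224, 15, 10, 1, 2, 35, 12.0),
        ("sim_g", "simulator", "PCV", 15.446, 16, 10, 1, 2, 35, 12.0),
    ]
    rows = []
    for study, cat, mode, mp, rr, peep, ie_i, ie_e, c_ml, raw in spec_rows:
        e = 1000.0 / c_ml
        ie = ie_i / ie_e
        vt = _invert_vt(mp, rr, e, raw, ie, peep)
        t_insp = 60.0 / rr * ie / (1.0 + ie)
        pplat = peep + vt * e
        ppeak = pplat + raw * vt / t_insp
        rows.append({
            "study": study, "category": cat, "mode": mode,
            "vt_ml": round(vt * 1000.0, 1), "rr": rr, "peep": peep,
            "ie_i": ie_i, "ie_e": ie_e,
            "ppeak": round(ppeak, 2), "pplat": round(pplat, 2),
            "compliance_ml_cmH2O": c_ml, "raw_cmH2O_s_L": raw,
        })
    return pd.DataFrame(rows, columns=LIT_COLUMNS)
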