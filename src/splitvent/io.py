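"""Readers and writers: waveform CSV + metadata sidecar, run configuration.

The canonical on-disk waveform format is a plain CSV with columns
``t_s, p_vent, q_vent, p_sim1, q_sim1, p_sim2, q_sim2`` (cmH2O, L/s), one
row per sample, accompanied by a YAML sidecar (same basename, ``.meta``
suffix) recording the full settings provenance and seed.  Spreadsheet
(xlsx) reading is supported for parity with bench exports, never written.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import (CircuitSpec, LungParams, VentilatorSettings,
                        WaveformRecord)

WAVEFORM_COLUMNS = ["t_s", "p_vent", "q_vent", "p_sim1", "q_sim1",
                    "p_sim2", "q_sim2"]


def _meta_path(path: os.PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta")


def _atomic_write(path: Path, write_fn) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_waveform(record: WaveformRecord, path: os.PathLike) -> None:
    """Write the canonical 7-column waveform CSV and its .meta sidecar."""
    path = Path(path)
    df = record.channels[WAVEFORM_COLUMNS]
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    meta = dict(record.metadata)
    meta.setdefault("sample_rate", record.sample_rate)
    meta.setdefault("seed", record.seed)
    _atomic_write(_meta_path(path),
                  lambda p: p.write_text(yaml.safe_dump(meta, sort_keys=False)))


def read_waveform(path: os.PathLike, dialect: str = "csv") -> WaveformRecord:
    """Read a waveform file back into a validated record.

    Cumulative volume channels are reconstructed by trapezoidal
    integration of the flows.  Raises on missing columns, non-uniform
    sampling, or a sampling-rate mismatch against the sidecar.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "spreadsheet":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"waveform file missing column(s): {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("waveform must hold at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling in time column")
    sample_rate = 1.0 / dt[0]

    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = yaml.safe_load(mp.read_text()) or {}
        meta_rate = meta.get("sample_rate")
        if meta_rate is not None and not np.isclose(meta_rate, sample_rate,
                                                    rtol=1e-6):
            raise ValueError(
                f"sampling-rate mismatch: file {sample_rate:.6g} Hz vs "
                f"metadata {meta_rate:.6g} Hz")
    df = df[WAVEFORM_COLUMNS].copy()
    for ch in ("vent", "sim1", "sim2"):
        q = df[f"q_{ch}"].to_numpy(dtype=float)
        v = np.concatenate(([0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * dt)))
        df[f"v_{ch}"] = v
    return WaveformRecord(sample_rate=sample_rate, channels=df,
                          metadata=meta, seed=int(meta.get("seed", 0)))


# ---------------------------------------------------------------------------
# run configuration

def config_to_objects(cfg: dict):
    """Build (settings, lung1, lung2, circuit, options) from a config dict."""
    settings = VentilatorSettings(**cfg["ventilator"])
    lung1 = LungParams(**cfg["lung1"])
    lung2 = LungParams(**cfg["lung2"])
    circuit = CircuitSpec(**cfg["circuit"])
    options = dict(cfg.get("options", {}))
    return settings, lung1, lung2, circuit, options


def objects_to_config(settings: VentilatorSettings, lung1: LungParams,
                      lung2: LungParams, circuit: CircuitSpec,
                      options: dict | None = None) -> dict:
    return {
        "ventilator": {
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
        "options": dict(options or {}),
    }


def load_config(path: os.PathLike) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path: os.PathLike) -> None:
    _atomic_write(Path(path),
                  lambda p: p.write_text(yaml.safe_dump(cfg, sort_keys=False)))
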