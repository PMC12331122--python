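"""Signal-processing chain for ventilator waveform recordings.

Mirrors the bench protocol: drop the first minute of each recording as a
calibration phase, segment the remainder into mechanical breaths by
inspiratory-flow onset, compute per-breath tidal volume (inspiratory flow
integral), peak and mean airway pressure and mechanical power, then
average over breaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .power import mp_from_loop
from .simulator import WaveformRecord

#: minimum inspiratory flow for breath-onset detection [L/s]
MIN_INSP_FLOW = 0.02
#: refractory hold after an onset before the next one may trigger [s]
REFRACTORY_S = 0.05


@dataclass(frozen=True)
class BreathSegment:
    """One mechanical breath on one channel (half-open sample indices)."""

    channel: str        # "vent" | "sim1" | "sim2"
    start: int
    boundary: int       # first expiratory sample (end of inspiration)
    end: int

    def __post_init__(self) -> None:
        if not (self.start < self.boundary < self.end):
            raise ValueError("need start < boundary < end")


@dataclass(frozen=True)
class BreathMetrics:
    """Per-breath waveform summary."""

    vt: float       # L
    p_peak: float   # cmH2O
    p_mean: float   # cmH2O
    mp: float       # J/min, inspiratory PV-loop power


def discard_calibration(record: WaveformRecord, discard: float = 60.0
                        ) -> WaveformRecord:
    """Drop the leading calibration phase of a recording."""
    if discard < 0:
        raise ValueError("discard must be >= 0")
    if discard == 0:
        return record
    if record.duration <= discard:
        raise ValueError(
            f"record duration {record.duration:.1f} s does not exceed the "
            f"discard window {discard:.1f} s")
    n_drop = int(round(discard * record.sample_rate))
    channels = record.channels.iloc[n_drop:].reset_index(drop=True)
    meta = dict(record.metadata)
    meta["discarded_s"] = meta.get("discarded_s", 0.0) + discard
    return WaveformRecord(sample_rate=record.sample_rate, channels=channels,
                          metadata=meta, seed=record.seed)


def segment_breaths(record: WaveformRecord, channel: str = "sim1",
                    min_insp_flow: float = MIN_INSP_FLOW
                    ) -> List[BreathSegment]:
    """Segment a recording into mechanical breaths on one flow channel.

    A breath starts at a positive-going crossing of ``min_insp_flow`` (with
    a refractory hold), runs to the next onset, and its inspiratory phase
    ends at the first non-positive flow sample.  A partial trailing breath
    is dropped; a leading sample already above threshold counts as an
    onset, so a record cut at a breath boundary yields exactly RR x minutes
    segments.
    """
    q = record.channels[f"q_{channel}"].to_numpy()
    if not np.any(q != 0.0):
        warnings.warn(f"flow channel q_{channel} is identically zero; "
                      "no breaths detected")
        return []
    refractory = int(round(REFRACTORY_S * record.sample_rate))

    above = q >= min_insp_flow
    onsets: List[int] = []
    if above[0]:
        onsets.append(0)
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    for idx in crossings:
        if onsets and idx - onsets[-1] < refractory:
            continue
        onsets.append(int(idx))
    if len(onsets) < 2:
        warnings.warn(f"fewer than two breath onsets on q_{channel}")
        return []

    period = float(np.median(np.diff(onsets)))
    bounds = list(onsets)
    # keep the trailing breath only if it is essentially complete
    if len(q) - onsets[-1] >= 0.9 * period:
        bounds.append(len(q))
    segments: List[BreathSegment] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        w = q[s:e]
        rel = np.flatnonzero(w[1:] <= 0.0) + 1
        if rel.size == 0:
            warnings.warn("breath without expiratory phase dropped")
            continue
        segments.append(BreathSegment(channel=channel, start=s,
                                      boundary=s + int(rel[0]), end=e))
    return segments


def breath_metrics(record: WaveformRecord, segment: BreathSegment,
                   rr: float) -> BreathMetrics:
    """Tidal volume, peak/mean pressure and PV-loop power of one breath.

    VT is the trapezoidal integral of inspiratory flow; p_mean is the
    time-weighted mean over the full cycle (conventional mean airway
    pressure); mechanical power is rr x the inspiratory integral of P dV.
    """
    if segment.end - segment.start < 3:
        raise ValueError("segment shorter than 3 samples")
    t = record.channels["t_s"].to_numpy()
    p = record.channels[f"p_{segment.channel}"].to_numpy()
    q = record.channels[f"q_{segment.channel}"].to_numpy()
    s, b, e = segment.start, segment.boundary, segment.end
    vt = float(np.trapezoid(q[s:b], t[s:b]))
    p_peak = float(np.max(p[s:e]))
    p_mean = float(np.trapezoid(p[s:e], t[s:e]) / (t[e - 1] - t[s]))
    mp = mp_from_loop(p[s:b], q[s:b], t[s:b], rr)
    return BreathMetrics(vt=vt, p_peak=p_peak, p_mean=p_mean, mp=mp)


@dataclass(frozen=True)
class SettingSummary:
    """Mean +- sample SD of the per-breath metrics for one setting."""

    table: pd.DataFrame     # index: channel; columns: <field>_{mean,sd}
    n_breaths: Dict[str, int]
    discarded_duration: float = 0.0


def summarize_setting(metrics: Dict[str, Sequence[BreathMetrics]],
                      discarded_duration: float = 0.0) -> SettingSummary:
    """Pool per-breath metrics into mean +- SD per channel."""
    rows = {}
    counts = {}
    for channel, ms in metrics.items():
        if len(ms) < 2:
            raise ValueError(
                f"channel {channel!r} has {len(ms)} breaths; need >= 2")
        arr = {f: np.array([getattr(m, f) for m in ms])
               for f in ("vt", "p_peak", "p_mean", "mp")}
        row = {}
        for f, v in arr.items():
            row[f"{f}_mean"] = float(np.mean(v))
            row[f"{f}_sd"] = float(np.std(v, ddof=1))
        rows[channel] = row
        counts[channel] = len(ms)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "channel"
    return SettingSummary(table=table, n_breaths=counts,
                          discarded_duration=discarded_duration)


def analyze_record(record: WaveformRecord, rr: float | None = None,
                   channels: Sequence[str] = ("vent", "sim1", "sim2"),
                   discard: float = 0.0) -> tuple[SettingSummary,
                                                  Dict[str, List[BreathMetrics]]]:
    """Full pipeline on one record: discard, segment, metrics, summary."""
    if discard > 0:
        record = discard_calibration(record, discard)
    if rr is None:
        rr = record.metadata.get("settings", {}).get("rr")
        if rr is None:
            raise ValueError("rr not given and absent from record metadata")
    per_channel: Dict[str, List[BreathMetrics]] = {}
    for ch in channels:
        segs = segment_breaths(record, ch)
        per_channel[ch] = [breath_metrics(record, s, rr) for s in segs]
    summary = summarize_setting(
        per_channel,
        discarded_duration=record.metadata.get("discarded_s", discard))
    return summary, per_channel
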