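#!/usr/bin/env python
"""Injury-threshold patterns over the circuit-2 grid.

Classifies every per-lung mechanical power against the 12 J/min
ventilation-induced lung injury threshold (with 17 and 22 J/min as the
liberal alternatives) and summarises where the model agrees with, and
departs from, the bench report: at RR 15 every pressure-controlled cell
stays safe while volume-controlled cells exceed 12 J/min; at RR 30 the
volume-controlled stiff-lung cells are injurious but the
pressure-controlled ones are not, because a passive 20 ml/cmH2O lung
driven at 10 cmH2O through 30 cmH2O.s/L receives far less volume than the
bench hardware delivered.
"""

from pathlib import Path

import pandas as pd

from splitvent import ProtocolGrid, classify_mp, run_grid

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grid = ProtocolGrid(circuit=2, duration=360.0, discard=60.0, base_seed=0)
    res = run_grid(grid)
    rows = []
    for _, r in res.iterrows():
        row = dict(r[["label", "mode", "rr", "c1_ml", "c2_ml",
                      "valve_setting", "channel", "vt_ml_mean", "mp_mean"]])
        for thr in (12.0, 17.0, 22.0):
            row[f"injurious_{int(thr)}"] = classify_mp(
                r["mp_mean"], thr).injurious
        rows.append(row)
    out = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "threshold_checks.csv", index=False)

    for rr in (15, 30):
        sub = out[out["rr"] == rr]
        n = sub["injurious_12"].sum()
        print(f"RR {rr}: {n}/{len(sub)} lung-cells above 12 J/min "
              f"(max {sub['mp_mean'].max():.1f} J/min, "
              f"all offenders {sorted(sub[sub['injurious_12']]['mode'].unique())})")
    sel = out[(out["rr"] == 30) & (out["valve_setting"] == 1)
              & (out["c1_ml"] == 20) & (out["c2_ml"] == 20)]
    print("\nRR 30, valve 1, C 20/20 per-lung power (J/min):")
    print(sel[["mode", "channel", "vt_ml_mean", "mp_mean", "injurious_12"]]
          .round(2).to_string(index=False))


if __name__ == "__main__":
    main()
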