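#!/usr/bin/env python
"""Volume diversion by progressive valve closure at the reference cell.

Simulates the circuit-2 family (PCV, RR 15, C 100/100) across all six
valve settings: closing the valve in front of lung 2 starves it of volume
while lung 1 gains slightly; the cumulative diverted volume at setting 6
is the headline ~100 ml figure.
"""

from pathlib import Path

import numpy as np

from splitvent import run_diversion_family

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    curve = run_diversion_family(duration=360.0, discard=60.0, base_seed=0)
    OUT.mkdir(exist_ok=True)
    curve.to_csv(OUT / "diversion_curve.csv", index=False)
    print(curve.round(2).to_string(index=False))

    r = np.corrcoef(curve["vt1_ml"], curve["vt2_ml"])[0, 1]
    print(f"\nvt1-vt2 correlation across settings: r = {r:.4f}")
    print(f"volume diverted away from lung 2 at setting 6: "
          f"{curve['dvt2_ml'].iloc[-1]:.1f} ml")


if __name__ == "__main__":
    main()
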