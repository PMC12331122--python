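#!/usr/bin/env python
"""Characterise the adjustable resistance valve across settings and flows.

Sweeps the six valve settings over 10-60 L/min, tabulating the pressure
drop, equivalent resistance and whether the combination stays inside the
ventilator's 40 mbar working ceiling (the bench could not assess the high
settings at 50-60 L/min), then refits the orifice coefficients from the
table as a self-check.
"""

from pathlib import Path

from splitvent import (OrificeValveModel, characterize_valve,
                       fit_orifice_coefficients)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = OrificeValveModel()
    table = characterize_valve(model, [10, 20, 30, 40, 50, 60])
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "valve_characterization.csv", index=False)

    infeasible = table[~table["feasible"]]
    print(f"{len(table)} setting x flow combinations; "
          f"{len(infeasible)} exceed the 40 mbar ceiling:")
    print(infeasible[["setting", "flow_lpm", "dp_cmh2o"]]
          .to_string(index=False))

    k_fit = fit_orifice_coefficients(table[table["feasible"]])
    print("\nOrifice coefficients refit from the feasible rows "
          "(k, cmH2O.s^2/L^2):")
    print(k_fit.round(2).to_string())


if __name__ == "__main__":
    main()
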