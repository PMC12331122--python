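# splitvent

One ventilator, two patients: a lumped-parameter simulation and analysis
toolkit for *ventilator splitting* — the crisis practice of ventilating two
passive patients from a single ICU ventilator through a shared breathing
circuit. The package reproduces a bench study of this practice at desk
scale: it simulates the two circuit designs (a plain split, and a split
with one-way valves plus an adjustable orifice resistance valve in front of
one patient), runs the full experimental protocol over ventilation mode,
respiratory rate, compliance pairing and valve setting, and quantifies the
safety question at the centre of the topic — how much **mechanical power**
each lung receives and whether it crosses the ventilation-induced lung
injury (VILI) threshold of 12 J/min.

## Model

Each simulated patient is a passive single-compartment lung obeying the
equation of motion

```
P_aw(t) = V(t)/C + Raw · V̇(t) + PEEP
```

with compliance `C` (20 or 100 ml/cmH₂O) and linear airway resistance
`Raw = 30 cmH₂O·s/L`. The two branches (3 m tubing limbs, 2 cmH₂O·s/L
each) couple at a common wye node carrying an effective circuit compliance
(9.2 ml/cmH₂O, calibrated — see `docs/methods.md`); the ventilator drives
the node either as a ramped pressure source (PCV, Pinsp 10 cmH₂O above
PEEP 8) or as a ramp-compensated constant-flow source delivering 450
ml/lung (VCV) with a hard 35 cmH₂O cap. In circuit-2, branch flows are
rectified by ideal one-way valves and branch 2 carries the adjustable
valve, an orifice `ΔP = k_s·Q²` whose coefficient grows with the setting
s = 1..6.

Mechanical power per lung is computed two ways:

* from the waveform, `MP = 0.098 · RR · ∫_insp P_aw dV` (J/min), and
* from the closed form
  `MP = 0.098 · RR · {ΔV²·[E_rs/2 + RR·(1+I:E)/(60·I:E)·Raw] + ΔV·PEEP}`.

## Worked example

Divert volume between the two lungs by closing the valve (reference cell:
PCV, RR 15, both compliances 100 ml/cmH₂O):

```
$ splitvent diversion --duration 360 --discard 60
 valve_setting  vt1_ml  vt2_ml  vt_vent_ml  cap_limited  dvt2_ml
             1  149.94  148.14      384.11        False     0.00
             2  150.00  143.99      380.05        False     4.14
             3  150.14  132.33      368.62        False    15.81
             4  150.44  108.51      345.27        False    39.63
             5  150.83   76.96      314.36        False    71.18
             6  151.19   48.46      286.41        False    99.68
```

Closing the valve starves lung 2 (148 → 48 ml, a diversion of ~100 ml)
while lung 1 gains only ~1 ml — the volume is mostly *lost*, not
redirected, under pressure-controlled ventilation; the two tidal volumes
are perfectly anticorrelated (r = −1.00). The literature survey:

```
$ splitvent litmp literature_table.csv
           n_settings  n_studies  mp_mean  mp_sd  sd_defined
category
human               6          2    34.98  12.71        True
animal              4          1    24.29   4.22        True
simulator           7          7     8.78   4.80        True
in-vivo vs simulator: t=5.50, p=0.0001
```

Every reported human and animal shared-ventilation setting exceeds the
12 J/min injury threshold, while simulator benches report several-fold
lower powers.

Other entry points: `splitvent simulate` (config → waveform CSV),
`splitvent analyze` (waveform → per-breath metrics), `splitvent grid`
(full protocol), `splitvent valvechar` (valve table). The numbered
scripts under `analysis/` run the complete study and write their tables to
`results/`.

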