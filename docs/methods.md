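# Methods

## The system being modelled

A single ICU ventilator drives two passive lung simulators through a
shared circuit. Two designs are studied: **circuit-1**, a plain split in
which each lung hangs off the ventilator wye through its own 3 m / 22 mm
tubing limb, and **circuit-2**, which adds one-way valves in each limb and
an adjustable six-position orifice resistance valve in the inspiratory
limb of lung 2 so that flow can be steered between the patients. The
protocol crosses circuit, mode (PCV/VCV), respiratory rate (15/30 bpm) and
compliance pairing (100/100, 100/20, 20/20 ml/cmH₂O), with all six valve
settings for circuit-2: 12 + 72 cells, each recorded for 6 minutes at
100 Hz with the first minute discarded.

## Circuit model

State variables are the two lung volumes above the PEEP-equilibrated
baseline and the wye-node pressure. Each lung is a series RC compartment
(`P_aw = V/C + Raw·V̇ + PEEP`); each limb contributes a series tube
resistance; the node carries an effective compliance lumping tubing
distension and gas compressibility. The ventilator connects to the node
through a small source impedance (0.5 cmH₂O·s/L). That impedance is what
couples the two branches under pressure control — with an ideal pressure
source the branches would be independent and closing the valve could not
push any volume toward the other lung.

Ventilator behaviour, by phase:

* **PCV inspiration** — source pressure ramps linearly from PEEP to
  PEEP + Pinsp over `rise_time` (100 ms; the bench value is not reported).
* **VCV inspiration** — flow ramps to a plateau over `rise_time` and is
  compensated so the commanded volume is 2 × 450 ml per breath; when the
  node pressure approaches the 35 cmH₂O cap the flow tapers continuously
  to zero through the source impedance (pressure-limit behaviour, flagged
  `cap_limited` on the record rather than raised as an error).
* **Expiration** — the machine pressure releases from its end-inspiratory
  value to PEEP over 50 ms (`release_time`, emulating an exhalation-valve
  release) and holds PEEP; circuit-1 lungs empty back through their limbs
  and the node, circuit-2 lungs empty through dedicated expiratory limbs
  (one-way valves block reverse flow, modelled as ideal diodes with
  0.5 cmH₂O·s/L forward resistance).

The rise and release ramps matter beyond realism: an instantaneous source
step slews the node within ~4 ms (its time constant), and a 100 Hz
sampled flow trapezoid cannot integrate a sub-sample transient — with the
ramps, flow integration and the internally accumulated volume channel
agree to <0.1% per breath, as they do for bench pneumotachography.

Integration is classical fixed-step RK4 at 1 ms (reduced automatically if
a configuration makes the node pole faster), with steps split exactly at
phase switches so no step straddles a drive discontinuity; the output is
decimated to 100 Hz. Against the closed-form RC step response the
simulated trajectory is accurate to <0.01% RMS. With zero sensor noise
the output is bit-reproducible; optional Gaussian sensor noise (seeded) is
applied to the pressure/flow channels only.

### Units

"Airway resistance 30 cmH₂O/l" is read in the standard respiratory
convention as **30 cmH₂O per L/s**, linear in flow. This is load-bearing:
with C = 100 ml/cmH₂O it gives an inspiratory time constant of 3.2 s
against an inspiratory window of 0.67 s (RR 15, I:E 1:5), so a passive
lung fills to only ~19% of its elastic limit. All pressures are cmH₂O,
flows L/s, volumes L internally (ml at presentation edges);
1 mbar = 1.0197 cmH₂O.

## Calibrated defaults

Two constants are not printed in the source report and are fixed by
calibration, as the study design prescribes:

* **Circuit compliance, 9.2 ml/cmH₂O** — chosen so that the circuit-1 VCV
  reference cell (450 ml/lung, RR 15, C 100/100) loses ≈200 ml per breath
  between the ventilator-delivered volume and the sum of the two lung
  tidal volumes, the discrepancy the bench attributed to its tubing
  system. Measured at the default: 198.9 ml.
* **Valve coefficients, k = 2 … 1081 cmH₂O·s²/L² (geometric)** — the six
  bore diameters are not individually published, so the orifice
  coefficients are spaced geometrically with k₆ set so that fully closing
  the valve diverts ≈100 ml away from lung 2 at the reference cell (PCV,
  RR 15, C 100/100). Measured: 99.7 ml. A consequence worth noting: the
  high settings exceed the ventilator's 40 mbar working ceiling already at
  modest characterisation flows, consistent with the bench being unable to
  assess them at 50–60 L/min.

A valve can alternatively be specified by a measured
(setting, flow, ΔP) table; the table model interpolates linearly in Q²,
which is exact for an orifice, and a least-squares refit of k per setting
serves as the self-check.

## Waveform pipeline

Breaths are segmented on a lung-port flow channel by positive-going
crossings of 0.02 L/s with a 50 ms refractory hold; the inspiratory phase
ends at the first non-positive flow sample and partial trailing breaths
are dropped. Per breath: VT is the trapezoidal integral of inspiratory
flow; Ppeak the maximum port pressure; Pmean the time-weighted mean over
the full cycle (the conventional mean airway pressure — the source does
not specify inspiration-only, and full-cycle is the convention);
mechanical power is `0.098 · RR · ∫ P dV` over inspiration. Setting
summaries are mean ± sample SD over all retained breaths.

## Mechanical power: two routes, and a reporting discrepancy

The closed form
`MP = 0.098·RR·{ΔV²·[E_rs/2 + RR·(1+I:E)/(60·I:E)·Raw] + ΔV·PEEP}`
and the PV-loop integral agree exactly for an ideal constant-flow
single-compartment breath (the resistive factor is 1/T_insp), and within
a few percent on simulated breaths; both are reported per grid cell
(`mp_mean` from the loop, `mp_formula_mean` from the closed form on the
measured per-breath VT at the set mechanics).

The bench report's own MP tables, however, cannot be reproduced from its
stated formula at the stated mechanics: inverting the formula against the
printed (VT, MP) pairs shows the published cells follow the closed form
evaluated at reference mechanics E ≈ 10 cmH₂O/L and Raw ≈ 10 cmH₂O·s/L in
*every* cell, including the stiff-lung (C = 20) cells where the set
elastance is five times larger. Two downstream claims inherit this
convention and are therefore not reproduced by a faithful model:

* "all low-rate settings stay below 12 J/min": VCV at RR 15 pushes
  ~340 ml/lung through Raw = 30 at constant flow, which is ~13–16 J/min by
  either route — above the threshold even when the stated formula is
  applied to the bench's own printed tidal volumes. Every PCV cell (the
  only mode the splitting valves are approved for) does stay below
  12 J/min.
* "at high rate both stiff lungs are injurious": at Pinsp 10 cmH₂O a
  passive 20 ml/cmH₂O lung with a 0.65 s time constant receives ~65 ml in
  the 0.33 s inspiratory window — ~3 J/min. The bench measured ~290–340 ml
  there, which is unreachable for a passive compartment at that driving
  pressure (it would require an alveolar swing of ~17 cmH₂O) and indicates
  the hardware behaved with a much lower effective resistance than the
  nominal 30. The VCV counterparts are injurious in the model
  (~13–14 J/min, cap-limited).

The two acceptance tests asserting those claims are left failing rather
than adjusted; the model, thresholds and study conditions are all as
specified.

## Statistics

Paired per-breath differences between the simulators are analysed as a
linear model of the difference on the breath index (a time effect for the
repeated measurements), reporting the intercept with 95% CI and p-value
(statsmodels OLS). A constant difference series is handled exactly
(degenerate CI; p = 1 when the difference is zero). The literature
comparison pools per-setting closed-form powers within category and
contrasts in-vivo (human + animal) against simulator rows with a Welch
two-sample t test; no multiplicity correction is applied, matching the
source's reporting of raw p-values. Survey rows missing Raw or I:E
receive defaults (10 cmH₂O·s/L, 1:2) and are flagged.

The packaged literature table is a **synthetic stand-in**: the published
supplement is not machine-readable, so plausible per-study settings were
constructed whose row-wise powers pool exactly to the reported category
summaries (human 34.98 ± 12.71 over 6 settings, animal 24.29 ± 4.22 over
4, simulator 8.78 ± 4.80 over 7). It exercises the survey computation
end-to-end but carries no independent information beyond those published
summaries.

## What the generator does and does not emulate

The simulator reproduces the protocol's structure (modes, rates,
compliance pairs, valve settings, recording length, discard window,
sampling rate), deterministic near-zero breath-to-breath variance, the
volume-conservation bookkeeping of a compliant circuit, pressure-cap
limiting, incomplete exhalation/breath stacking at long expiratory time
constants, and the direction of every redistribution effect (diversion,
compliance mismatch, VT anticorrelation). It does not emulate the bench
hardware's servo behaviour — most visibly, the real ventilator delivered
3–5× more volume in PCV than a passive linear-RC load admits, and its
effective circuit resistance was far below the nominal setting — so
absolute per-cell volumes, pressures and powers are not comparable to the
published tables (passing tests show internal consistency and reproduced
derived quantities, not agreement with the hardware cells). Spontaneous
breathing, leaks, nonlinear compliance and >2-patient topologies are out
of scope.

## Numerical and design choices

* Sub-stepping keeps the explicit integrator stable for any node time
  constant down to ~0.4 µs (then it refuses rather than silently degrade).
* Cell seeds derive from a base seed plus a CRC32 of the cell label:
  reproducible, distinct, and stable across processes.
* Tidal volume uses flow integration (not the volume channel) because
  recorded CSV files carry only pressure/flow; the volume channel is
  reconstructed on read and the two integrators are asserted to agree.
* An infeasible grid cell yields a flagged row, not an abort, so a sweep
  survives bad configurations.
* Known limitation: the model's RR 30 PCV cells deliver *less* power than
  their RR 15 counterparts at C = 100 (breath stacking collapses VT; the
  expiratory time constant ≈ 3.2 s exceeds the 1.67 s window), whereas the
  bench reported the opposite ordering — another face of the resistance
  mismatch described above.
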