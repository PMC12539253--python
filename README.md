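# microdrive

Computational toolkit for a chronic rat electrophysiology implant whose
probes (Neuropixels-style linear shanks) are repositioned after surgery by a
screw-driven shuttle turned through a planetary-geared screwdriver. The
package covers everything in that workflow that is arithmetic rather than
surgery: converting screwdriver turns to micron-scale probe travel, keeping a
verifiable ledger of the probe tip's depth across weeks of micro-adjustments,
correcting 3D-printing tolerance by calibration, bench-testing probe gain in
a saline bath, and running the offline pre-processing + threshold
spike-detection chain used to evaluate the recordings. A seeded synthetic
recording generator provides ground-truth fixtures for all of it, so the
whole pipeline is testable without any acquisition hardware.

It is written for labs running chronic implants who want the bookkeeping —
where is my probe tip, how many turns do I make today, is my probe's gain
still in spec, did that channel really spike — to be reproducible code
instead of a spreadsheet.

## The model

**Kinematics.** A drive screw of pitch *P* (mm per full rotation) moves the
shuttle by

```
D = P · T_dr                      (direct screw turns)
D = P · T_in · r                  (turns at the geared screwdriver input)
```

where the turn ratio of one planetary stage (sun input, carrier output,
fixed ring) is `r_stage = S / (R + S)` for sun/ring tooth counts `S`, `R`,
and cascaded stages multiply. The kit's two 8/32 stages give
`r = (1/5)² = 1/25`, so with `P = 0.3 mm` one input turn moves the probe
**0.012 mm**. Ratios are exact rationals internally (`fractions.Fraction`),
converted to floating point only at the millimetre boundary.

**Depth ledger.** With the dorsoventral (DV) coordinate negative below the
surface, the shank is drawn `L0 = |DV0| + A + B` before implantation (skull
thickness *A*, implant bottom wall *B* = 0.5 mm), and the tip depth after
`n` micro-adjustments is `DV = DV0 + Σ Dᵢ`, recomputable from the append-only
record at any time. Calibration against a 3 mm reference mark yields error
turns `ET = counted − 10` and error distance `ED = P · ET`.

**Signal chain.** Artifact masking (|z| ≥ 10 against the whole channel, ±2 ms
guard, median replacement) → local common averaging (mean of up to 7
neighboring channels per side subtracted) → zero-phase 2nd-order Butterworth
band-pass 300–5000 Hz → threshold detection at −80 μV with a secondary
|z| ≥ 1 filter, 1.7 ms inverted clips centered on the trough, and
cross-channel footprints over the nearest 4 channels per side.

## Worked example

```
$ microdrive gears
stage 1: sun 8, ring 32 -> 5:1
stage 2: sun 8, ring 32 -> 5:1
total ratio: 25:1
travel per input turn: 0.012 mm
```

Two cascaded 5:1 planetary stages make the 25:1 screwdriver; one input turn
advances the 0.3 mm pitch screw by 12 μm.

```
$ microdrive ledger init --out ledger.csv --dv0 -1.4 --skull 0.7
draw length L0: 2.600 mm (8.67 direct turns)
ledger written to ledger.csv; DV0 = -1.4 mm

$ microdrive ledger plan --ledger ledger.csv --target -1.46
+5 geared input turns -> -1.4600 mm DV (residual +0.0 μm)

$ microdrive ledger adjust --ledger ledger.csv --turns 5
record 0: -0.0600 mm (+5.000 geared turns); tip now at -1.4600 mm DV
```

Implanting at −1.4 mm DV through a 0.7 mm skull requires a 2.6 mm draw
(8.67 direct turns); descending a further 60 μm takes exactly 5 geared
turns, leaving the tip at −1.46 mm DV.

```
$ microdrive calib --counted 11.5
error turns ET = 1.5; error distance ED = 0.45 mm (pre-turn ET after full retraction to correct)

$ microdrive gaintest --seed 1
estimated gain 1021.9 (nominal 1000); deviation 2.19% (<=10% criterion: PASS)
```

If the calibration mark needed 11.5 turns instead of 10, the print-tolerance
gap is 0.45 mm, corrected by pre-turning 1.5 turns after full retraction.
The synthetic saline-bath bench (100 pulses of 100 μs, 250 ms apart)
recovers the nominal gain of 1000 within 2.2%, well inside the 10% criterion.

Recordings flow the same way from Python:

```python
from microdrive import SimulationPlan, SpikeInjection, default_template
from microdrive import simulate_recording, run_chain, evaluate_detection

tpl = default_template(30_000, trough_uv=-150.0, decay_per_channel=0.4)
plan = SimulationPlan(
    n_channels=16, duration_s=2.0, noise_sd_uv=8.0, seed=7,
    spikes=(SpikeInjection(channel=5, time_s=1.0, template=tpl),),
)
block, truth = simulate_recording(plan)
events_by_channel, footprints, audit = run_chain(block)
recall, precision, _ = evaluate_detection(
    [e for evs in events_by_channel.values() for e in evs], truth, 30
)
```

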