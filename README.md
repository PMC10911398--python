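# rrpkinetics

Kinetic dissection of the readily releasable pool (RRP) of synaptic
vesicles from patch-clamp observables, for electrophysiologists and
modellers studying presynaptic release — in particular SNARE-machinery
variants (e.g. SNAP25 disease mutations) whose phenotypes mix changes
in vesicle priming, depriming, and fusion.

## The model

The RRP is a single compartment filled by priming and drained by
depriming and spontaneous fusion,

```
dRRP/dt = k1 − (k−1 + kf)·RRP
```

with `k1` in vesicles/s and `k−1`, `kf` per-vesicle hazards (1/s). At
steady state `RRP∞ = k1/(k−1+kf)` and the mEPSC rate is
`r_mini = kf·RRP∞`. Hypertonic sucrose multiplies `kf` by a large
fold-increase `N_suc`, so the late plateau of the sucrose response
reports on `k1` (exactly: `kf·N_suc·k1/(k−1+kf·N_suc)`). Measuring
the RRP charge, the mini rate, and the sucrose plateau therefore
determines all three rate constants. Comparing a mutant's rates to a
reference converts, via Arrhenius (`ΔEa = RT·ln(k_ref/k_mut)`, with
RT = 2.479 kJ/mol at room temperature), into an energy landscape over
the states *pre-primed → priming barrier → RRP → fusion barrier*; a
saturating electrostatic model maps per-vesicle fusion rates to
equivalent SNARE-surface charges.

The package provides:

* `rrpkinetics.synthetic` — exact Gillespie simulation of the pool
  (including sucrose applications with solution-exchange ramps and AP
  trains) and rendering of fusion events into realistic 20-kHz current
  traces;
* `rrpkinetics.traces` — variance–mean (shot-noise) baseline
  correction, RRP-transient/plateau integration, a spectral
  (Campbell) plateau-rate estimator, mini detection with
  dead-time correction, cumulative-charge train back-extrapolation,
  synchronous/asynchronous decomposition;
* `rrpkinetics.pool` — closed-form forward model and three inversion
  routines (idealised, finite-`N_suc`, and protocol-aware);
* `rrpkinetics.energy` — Arrhenius energy offsets and landscape
  assembly;
* `rrpkinetics.electrostatics` — the saturating charge→rate curve, its
  exact inverse, charge separations, and peak-rate downscaling;
* a `rrpkinetics` CLI (`simulate`, `analyze`, `landscape`, `charges`)
  tying the stages into a reproducible, manifest-driven pipeline.

## Worked example

Simulate one wildtype-like autaptic cell (60 s spontaneous recording
plus a 5-s sucrose application with a −20 pA leak shift) and run the
full analysis:

```python
from rrpkinetics import pipeline, energy
from rrpkinetics.reference import REFERENCE_RATES

wt = REFERENCE_RATES["WT"]          # (k1, k−1, kf) = (385.6, 0.0903, 0.000844)
rec = pipeline.simulate_cell(wt, seed=1, condition="WT")
row = pipeline.analyze_cell(rec)
```

which prints (seed 1):

```
mini rate      3.679 events/s
RRP charge     200.4 pC (4187 vesicles)
k1             367.8 vesicles/s
k_minus1       0.0870 1/s
kf             0.000879 1/s
```

The detected mini rate sits near the model's expectation
`kf·RRP∞ ≈ 3.57 events/s`; the estimated triple recovers the
generating rates to within this single cell's sampling error (cohorts
of 50 cells recover them to ~1%). Comparing the D166Y parameter set
against its parallel wildtype control:

```python
ls = energy.build_landscape(REFERENCE_RATES["WT_D166Y_set"],
                            REFERENCE_RATES["D166Y"],
                            reference_label="WT", mutant_label="D166Y")
```

```
priming TS     +2.496 kBT
RRP state      +1.164 kBT
fusion TS      -3.319 kBT
```

i.e. the mutant raises the priming barrier (fewer vesicles prime),
destabilises the RRP state, and lowers the fusion barrier (more
spontaneous fusion) — a mixed loss- and gain-of-function landscape.

The same analyses run from the shell:

```
rrpkinetics simulate  --config examples/conditions.yaml --out runs/demo
rrpkinetics analyze   --in runs/demo --out summary.csv --rates-out rates.csv
rrpkinetics landscape --rates rates.csv --reference WT --out landscape.csv
rrpkinetics charges   --rates rates.csv --out charges.csv
```

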