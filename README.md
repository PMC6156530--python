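# alternanslab

Cardiac alternans — the beat-to-beat alternation of action-potential
duration (APD) and calcium-transient amplitude at a fixed pacing rate — is a
precursor of ventricular arrhythmia, and in calcium-driven alternans the
oscillation originates in sarcoplasmic-reticulum (SR) calcium cycling.
`alternanslab` is a simulation laboratory for one specific mechanism:
**SR calcium-cycling refractoriness**, in which a steep junctional-SR (JSR)
load–release relationship combines with rate-limited NSR→JSR refilling so
that, at fast pacing, a large release leaves the JSR under-refilled, the
next release is small, and a period-2 oscillation locks in.

The package provides, for modellers and cardiac-dynamics researchers:

* a reduced compartmental calcium-cycling myocyte model (trigger influx →
  subspace → CICR from the JSR → myoplasm → SERCA reuptake to the NSR →
  NSR→JSR transfer, with CaMKII-enhanced reuptake and a stylized
  calcium-coupled action potential), integrated with a numba-compiled RK4
  core fast enough for 2500-beat protocols, parameter scans and
  populations of models;
* pacing protocols with a beat-pair quasi-stability criterion (< 0.2% drift
  per 100 beats), snapshotting, and two-phase pre-pace/modify/continue
  scans;
* per-beat metrics: APD90, CaT amplitude, JSR depletion fraction
  `(Ca_JSR,start − min Ca_JSR)/Ca_JSR,start`, release time-to-peak and
  duration, flux integrals;
* a triangular release clamp and the **alternans threshold** search — the
  largest total release for which the JSR refills within one AP, mapped
  over release duration × time-to-peak;
* scans of NSR→JSR diffusion, release time constant (with compensatory
  trigger rescaling that keeps total release flat), and trigger conductance
  as a release-magnitude proxy;
* bifurcation diagrams over pacing rate with **fork/eye** alternans
  classification and the eye-closure ↔ full-JSR-depletion co-occurrence
  analysis on a synthetic conductance-varied population.

The beat-to-beat mechanism, in map form: with beat-initial JSR load `L_n`,
released amount `R(L_n)` growing steeply with load, and refilling toward the
NSR with effective time constant `τ_tr/β_jsr`, the stable-state map slope is
approximately `−e^(−T/τ_eff)·(R′−1)`; alternans requires steep release
(`R′ > 1`) *and* incomplete refilling (`T ≲ τ_eff`), which is why slowed
NSR→JSR transfer promotes alternans and accelerated transfer suppresses it,
and why full functional depletion (which flattens `R`) extinguishes it.

## Worked example

Pace the calibrated default cell at a slow and a fast rate and look at the
final two beats:

```python
from alternanslab import ModelParameters, ModelState, pace

params = ModelParameters.default()

slow = pace(ModelState(), params, bcl=400.0, n_beats=1500)
fast = pace(ModelState(), params, bcl=260.0, n_beats=1500)
for name, r in [("bcl 400", slow), ("bcl 260", fast)]:
    a = r.alternans()
    print(f"{name}: APD alternans {a['d_apd']:.1f} ms, "
          f"CaT alternans {a['d_cat']:.6f} mM, "
          f"quasi-stable {r.quasi_stable}")
```

```
bcl 400: APD alternans 0.0 ms, CaT alternans 0.000 mM, quasi-stable True
bcl 260: APD alternans 7.7 ms, CaT alternans 0.000193 mM, quasi-stable True
```

At bcl 400 ms the cell is period-1; at 260 ms it shows sustained APD and
calcium-transient alternans (the quasi-stability criterion is built from
beat-pair extrema precisely so that a stationary period-2 state counts as
stable). Scaling the NSR→JSR diffusion time constant moves the cell across
the alternans boundary:

```python
two_phase = pace(fast.end_state, params.scaled(tau_tr=0.7), 260.0, 800)
print(two_phase.alternans()["d_apd"])   # -> 0.0  (faster refilling: no alternans)
```

The same protocols are scriptable from the shell via the `alternans-lab`
CLI (`pace`, `scan-tau-tr`, `scan-release-tau`, `scan-ical`,
`threshold-map`, `bifurcation`, `population`, `release-linearity`, or `run`
with an experiment YAML); each writes tidy CSV plus a JSON run manifest.

## Layout

```
src/alternanslab/
  params.py      model parameters, validation, scaling, YAML config
  model.py       state containers, single-beat integration, conservation
  _kernels.py    numba RK4 core and per-beat measurement kernels
  pacing.py      pacing protocols, quasi-stability, snapshots, two-phase
  metrics.py     APD90, alternans amplitude, depletion, flux integrals
  clamp.py       triangular release clamp, alternans-threshold map
  scans.py       tau_tr / release-tau / I_CaL scans, release linearity
  population.py  bifurcation diagrams, fork/eye classification, population
  cli.py         alternans-lab command-line interface
docs/methods.md  model equations, assumptions, numerics, calibration
```
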