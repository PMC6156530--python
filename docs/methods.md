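# Methods

## The model

`alternanslab` implements a reduced compartmental model of calcium cycling in
a paced ventricular myocyte, built to expose the mechanism by which
sarcoplasmic-reticulum (SR) calcium release shapes repolarization and
calcium-transient alternans: a steep junctional-SR (JSR) load–release
relationship combined with rate-limited NSR→JSR refilling ("SR calcium
cycling refractoriness"). It is not a full ionic model — no sodium or
potassium currents are represented — but it preserves the calcium-handling
architecture of detailed models: trigger influx (an L-type calcium current
surrogate) into a junctional subspace, calcium-induced calcium release from
the JSR through a RyR gate, diffusion to the bulk myoplasm, SERCA reuptake
into the network SR (NSR), and NSR→JSR transfer along the concentration
gradient, with CaMKII-enhanced reuptake.

State variables (free Ca²⁺ in mM, activities in [0, 1]):

| variable | meaning |
|---|---|
| `ca_myo` | bulk myoplasmic calcium |
| `ca_ss` | junctional-subspace calcium |
| `ca_nsr` | network-SR calcium |
| `ca_jsr` | junctional-SR calcium |
| `ryr_open` | RyR release-gate activity |
| `camkii` | CaMKII activity |

Fluxes (each per ms in its own compartment's volume; volume ratios
`v_myo : v_ss : v_nsr : v_jsr` convert between compartments so total calcium
is conserved when membrane fluxes are off):

* trigger: `J_CaL = g_cal · i_cal_bar · (t/τ_trig)·e^(1−t/τ_trig) ·
  k_cdi/(k_cdi + ca_ss)` — a stereotyped early pulse launched by each
  stimulus, with calcium-dependent inactivation sensed on subspace calcium;
* release: `J_rel = g_rel · ryr_open · (ca_jsr − ca_ss)`;
* RyR gate: `d ryr/dt = drive·(1−ryr)/τ_act − ryr/τ_rel` with
  `drive = (J_CaL/k_trig)^n_trig · ca_jsr^h / (ca_jsr^h + k_rel^h)`;
* transfer: `J_tr = (ca_nsr − ca_jsr)/τ_tr`, attenuated by the
  release-refractory availability factor described below;
* reuptake: `J_up = v_up · (1 + camkii_gain·camkii) · (1 − ca_nsr/nsr_max) ·
  ca_myo²/(ca_myo² + k_up²)`;
* subspace diffusion `J_diff = (ca_ss − ca_myo)/τ_diff`, JSR leak
  `J_leak = g_leak_jsr·(ca_jsr − ca_myo)`, and a linear NCX-like extrusion
  `g_ncx·ca_myo` balanced by a constant background influx `ca_bg`.

Four modelling choices deserve comment because they differ from the most
obvious construction:

1. **The load–release steepness lives in the gate drive, not the release
   flux.** With a Hill factor on the instantaneous `ca_jsr` multiplying the
   release flux itself, release always terminates at a fixed load floor, so
   the amount released rises at most one-for-one with the starting load —
   too shallow to destabilize the beat-to-beat map. Placing the Hill factor
   in the gate *drive* means the gate opening is set by the JSR load sampled
   at trigger time (luminal RyR sensitization): the released amount then
   grows superlinearly with starting load, which is the steep load–release
   relationship the alternans mechanism requires. The measured log–log slope
   of peak release vs load exceeds 1 over the operating range.
2. **SERCA carries a luminal back-pressure factor** `(1 − ca_nsr/nsr_max)`.
   Without it the SR load drifts to whatever level saturates the release
   Hill curve, parking the cell on the flat part of the load–release curve
   where alternans cannot form. The back-pressure (a thermodynamic pump
   limit) bounds the NSR and lets the JSR operating point sit on the steep
   part of the curve.
3. **The trigger acts cooperatively on the gate** (`(J_CaL/k_trig)^n_trig`,
   default cooperativity ≈ 2–3). Local calcium-induced calcium release is
   strongly supra-linear in the trigger: weak triggers recruit
   disproportionately few release units. In the cell-level model this is
   what lets release *inhibition* (a low trigger-conductance multiplier)
   abolish alternans — with a linear drive, the whole-cell calcium balance
   simply re-equilibrates and the oscillation survives — and what lets
   release *potentiation* push every beat to functional depletion.
4. **Refilling is release-refractory.** While the RyR gate is open over a
   nearly empty JSR, calcium transferred from the NSR is not retained (it
   is re-released immediately), so net refill is gated by an availability
   factor that engages only when release is active *and* the free JSR is
   below `k_tr_stall`; once the gate closes, refill proceeds at the full
   gradient-driven rate, so an emptied JSR always recovers. This is the
   junctional counterpart of spark restitution — a release unit refills
   after its release terminates — and it is what allows the per-beat JSR
   minimum to approach zero (full functional depletion) even though
   refilling is fast enough to restore the load within one cycle.

Buffering is instantaneous: each compartment's free-calcium rate is scaled
by a fraction-free factor `beta` (the NSR is treated as unbuffered). One
consequence worth keeping in mind when reading time constants: the
*effective* JSR refill time constant is `τ_tr/β_jsr`, several-fold longer
than `τ_tr` itself. That rate-limited refilling is the heart of the
mechanism.

## Membrane potential and APD coupling

The calcium subsystem does not depend on the action-potential waveform
beyond the stimulus timing (the trigger pulse is over within ~20 ms), so the
membrane potential is a pure readout: a stylized template with an
instantaneous upstroke (`v_rest` → `v_peak`) and a linear repolarization
ramp whose APD90 equals the coupled APD

    APD_n = clamp(apd_base + gamma_ca · (CaT_n − cat_ref), apd_min, apd_max),

where `CaT_n` is the calcium-transient amplitude (peak − pre-stimulus
`ca_myo`) of the same beat. This hybrid coupling stands in for the
NCX-mediated translation of calcium alternans into repolarization
alternans; `gamma_ca` sets the mV-free exchange rate between the two units
(ms of APD per mM of CaT). A beat whose coupled APD reaches the cycle length
is flagged non-repolarizing (2:1-block-like) and, in bifurcation scans,
terminates the swept range for that cell.

## Numerics

The production integrator is a fixed-step classical RK4 compiled with numba
(default `dt = 0.05 ms`; `dt = 0.1 ms` for the population study). The model
is non-stiff by construction — the fastest time constants (trigger pulse,
subspace diffusion, gate activation) are ≥ 0.6 ms — and the pacing
protocols need tens of millions of beats-steps, which rules out per-beat
adaptive stepping at acceptable cost. An adaptive path
(`integrate_beat(..., method="adaptive")`, scipy LSODA at rtol 1e-6 / atol
1e-9) is retained and cross-validated against the RK4 oracle at
`dt = 0.005 ms`: end-of-beat concentrations agree to < 0.5%. Calcium
conservation with membrane fluxes disabled holds to < 1e-6 relative over 10
beats. Flux integrals use the trapezoid rule on the integration grid; the
end-of-step fluxes reuse the RK4 stage-4 evaluation, an O(h²)-accurate
shortcut of the same order as the quadrature. APD90 crossings on traces are
located by linear interpolation.

Per-beat release-shape features: time-to-peak is the grid argmax of
`J_rel`; release duration is measured from onset (first sample ≥ 5% of
peak) to 90% decay (first post-peak sample < 10% of peak).

## Protocols

* **Pacing / quasi-stability.** Cells are paced 2500 beats by default. The
  cell is quasi-stable when, for each tracked variable (APD surrogate,
  `ca_myo`, `ca_nsr`, `ca_jsr`, CaMKII), the maxima and minima over
  consecutive beat *pairs* drift less than 0.2% per 100 beats; pairing lets
  a stationary period-2 alternans count as stable. The drift estimator is a
  least-squares slope over a 200-beat window (the criterion itself does not
  prescribe an estimator or window; both are configurable).
* **Two-phase scans.** Pre-pace with native parameters, snapshot, apply a
  multiplier (e.g. τ_tr × 0.6…1.4), continue pacing, measure end-state
  alternans from the final two beats. Conditions are independent.
* **Release-dynamics scan with I_CaL compensation.** Scaling the release
  time constant (the `tau_rel` multiplier scales gate activation and
  inactivation together) slightly changes total release; a compensation
  multiplier on `g_cal` is recomputed per condition by Brent root finding so
  the 2-AP release integral matches baseline within 0.5%.
* **Triangular release clamp.** From a bcl-400 pre-paced snapshot, one AP is
  simulated with `J_rel` replaced by a triangle (onset 1 ms after the
  stimulus; parameters: duration, time-to-peak, total) and the JSR leak set
  to zero so the imposed area is the exact total release. "Refilled" means
  `jsr_final ≥ jsr_initial − 1e-9 mM` within a 400 ms horizon. The
  *alternans threshold* of a shape is the largest refilling total, found by
  bisection (tolerance 0.1% of the bracket) with geometric bracket
  expansion; a non-monotone refill flag is reported, not bisected. The
  imposed flux tapers smoothly to zero below 0.02 mM free JSR calcium so an
  oversized triangle cannot withdraw calcium that is not there (the
  bookkeeping identity `Δjsr = β_jsr·(∫J_tr − total)` holds whenever the
  taper is not engaged).
* **Bifurcation / population.** Descending bcl sweep (default 600→250 ms in
  50 ms steps), recording the last two beats per bcl; classification uses an
  APD-split threshold ε = 2 ms (the scale of natural APD variability):
  `none` / `fork` (split persists at all faster rates) / `eye` (split closes
  again). Full functional depletion means depletion fraction ≥ 0.99 in both
  final beats. The synthetic population samples independent log-normal
  multipliers (σ = 0.15) on `g_cal`, `v_up`, `tau_rel`, `tau_tr`,
  `gamma_ca`.

## Calibration of the default cell

The default parameter set (config/defaults.yaml) was calibrated so that the
baseline cell reproduces the qualitative experimental pattern that defines
the mechanism, rather than any quantitative recording: no alternans at
bcl 400 ms; sustained APD+CaT alternans at bcl 260 ms; alternans abolished
by accelerating NSR→JSR transfer (τ_tr × 0.7) and enlarged by slowing it
(τ_tr × 1.3); no alternans at bcl 300 ms unless transfer is slowed further;
release inhibition (low trigger) abolishes alternans; strong release
potentiation (high trigger) yields transient alternans that vanishes at the
stable state with full JSR depletion every beat, rising NSR load and rising
CaMKII. Calibration was a randomized search over the release, reuptake and
trigger parameters scored on exactly that pattern, followed by local
refinement that added the release-clamp shape objectives (threshold and
refill-integral gradients along the triangle-shape grid).

## Problem sizes

The shipped tests and the acceptance script use scaled-down protocol sizes
chosen to preserve the phenomena: 1500-beat pre-pacing plus 800-beat
continuation for the two-phase scans (the slow variables of the reduced
model settle within a few hundred beats), 1800 beats for the
release-magnitude sweep, a 5 ms release-shape grid for the threshold map,
and a 200-cell population on a 450→250 ms grid at 150 beats per bcl
(dt 0.15 ms) with warm-started continuation between cycle lengths.

## What the synthetic data does and does not show

All inputs are generated by the model itself; there is no external data.
Passing tests therefore demonstrate internal consistency of the mechanism —
that a steep load–release relationship plus rate-limited JSR refilling
produces rate-dependent alternans with exactly the documented responses to
release dynamics and magnitude — not that any particular species' myocyte
is quantitatively described. Known idealizations: no sodium/potassium
dynamics or restitution coupling (APD is a calcium readout, so
APD-restitution-driven alternans is out of scope by construction); linear
NCX without voltage dependence; instantaneous buffering (no calsequestrin
kinetics); deterministic RyR gating (no sparks); a single lumped release
compartment (no subcellular discordance).

Two quantitative limitations of the calibrated cell are worth stating
plainly, because the code that measures them is fully functional and the
limitation is a property of the model, not of the pipeline:

1. **Depletion depth.** Because release terminates smoothly (the gate
   closes with a finite time constant while gradient-driven refilling
   continues), the per-beat free-JSR minimum is set by a release/refill
   balance. In the potentiated-release regime the stable state reaches
   depletion fractions of ~0.86 at trigger multiplier 2 (~0.98 at extreme
   multipliers), with the mechanism signature fully present — transient
   alternans that dies out, every-beat near-complete depletion, rising NSR
   load and rising CaMKII. A model with abrupt, depletion-triggered release
   termination would push the measured fraction above 0.99; this model
   deliberately does not emulate that abrupt cutoff, so classifications
   keyed to the 0.99 threshold (`FULL_DEPLETION_THRESHOLD`) report "not
   fully depleted" for states that are functionally depleted in every
   mechanistic sense. The threshold is a single configurable constant.
2. **Fork-type dominance in the population.** In the calibrated cell,
   faster pacing deepens the alternating-release asymmetry rather than
   saturating the depletion, so bifurcation diagrams over the scanned bcl
   range are fork-type; the synthetic population (log-normal multipliers,
   sigma 0.15) yields fork and no-alternans cells but no eye-type cells.
   Trigger potentiation at a fixed rate does close the alternans "eye"
   through near-complete depletion (the release-magnitude sweep), but
   rate-driven closure — alternans vanishing as pacing accelerates — would
   require the reuptake/refilling gain to grow faster with rate than this
   parameterization provides. The classification and co-occurrence
   machinery (fork/eye labels, closure-bcl vs full-depletion-bcl) is
   exercised against synthetic bifurcation diagrams in the unit tests.
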