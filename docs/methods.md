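# Methods

## The model

`lqt8sim` simulates human ventricular electrophysiology with the ten
Tusscher–Panfilov 2006 (TP06) myocyte model: 12 Hodgkin–Huxley gates, a
sarcoplasmic-reticulum (SR) release recovery gate, and 5 ionic
concentrations per cell.  Transmural heterogeneity enters through the
transient-outward (`g_to`) and slow delayed-rectifier (`g_Ks`) conductances
and the Ito inactivation-gate kinetics of the endocardial class, exactly as
TP06 defines the ENDO / MCELL / EPI phenotypes.  Tissue is the isotropic
monodomain equation `Cm dVm/dt = D lap(Vm) − Iion`, marched with forward
Euler at `dt = 0.02 ms` (3-point/5-point Laplacians, no-flux mirror
boundaries).  All model constants are in
`src/lqt8sim/data/tp06_constants.tsv` with units and provenance notes.

Two deliberate dialect choices, both recorded here because published TP06
sources disagree among themselves:

1. **f2 gate.**  The printed TP06 equations and the authors' later code
   differ in the slow voltage-inactivation gate (steady-state floor 0.25 vs
   0.33, different time-constant coefficients).  We use the printed-equation
   version.  Under our SR dialect (below) it reproduces the target study's
   wild-type ENDO APD90 (271.6 vs 267.8 ms) and diastolic potential (−85.70
   vs −85.83 mV) far better than the code dialect (302.5 ms).

2. **SR release + leak.**  The study formulates the calcium-induced calcium
   release as the combination of SR release and SR leak; the exact
   supplementary constants are not available to us.  Our dialect makes two
   changes to stock TP06:
   * the SR leak (unchanged rate constant, 3.6×10⁻⁴/ms) drains into the
     **dyadic subspace** through the release pathway rather than into the
     bulk cytosol.  This single re-routing reproduces the study's printed
     wild-type Cai transient amplitude (4.0×10⁻⁴ mM, exact) and AP-phase
     peak |I_CaL| (4.22 vs 4.28 pA/pF), which is why we adopted it;
   * a release-gate **overload sensitization**: the activation rate of the
     release gate rises steeply (×1500, tanh threshold of width 0.005 mM)
     once the SR load crosses `K_over = 3.97 mM`.  Because the subspace
     leak keeps diastolic subspace calcium mildly elevated, crossing the
     threshold triggers regenerative spontaneous release, the inward
     sodium–calcium exchange current it drives, and hence delayed
     afterdepolarizations.  `K_over` was placed once, inside the SR-load gap
     separating the highest non-DAD condition from the R858H midmyocardial
     cell at PCL 500 ms (3.93–4.02 mM across the whole allele × class × rate
     grid), which is the calibration the reported binary afterdepolarization
     phenotype permits.  No other quantity was used to tune it.

## Variant I_CaL construction

Each CACNA1C allele is a six-parameter record (`csf`, activation
midpoint/slope, inactivation midpoint/slope, `tcsf`).  R858H carries the
experimentally reported ~2 mV negative activation shift and ~2 mV positive
inactivation shift; the other alleles keep wild-type kinetics because no
kinetic data are printed for them.  `tcsf` (inactivation time-constant
scale) stays 1 for all alleles for the same reason.  Conductance scale
factors are calibrated by bisection (csf ∈ [0.01, 10], 10⁻⁴ relative
tolerance) so that the simulated voltage-clamp I–V minimum reproduces the
experimental peak-density fold ratio vs WT (0.86 / 1.04 / 1.08 / 1.19 /
1.54).  The clamp protocol holds at −90 mV and steps 300 ms to −40…+60 mV in
10-mV increments with 3-s recovery; during clamp the calcium subsystem runs
with the full model, so calcium-dependent inactivation is driven by the
model's own subspace calcium.  Calibrated values are frozen in
`data/ical_variants.tsv` with per-row provenance.  Because subspace-calcium
feedback makes the peak sub-linear in conductance, the calibrated csf values
(e.g. 1.222 for the 1.19-fold allele) sit slightly above the bare ratios.

## Protocols and measurement definitions

* **APD90** — from the maximum-upstroke-velocity instant to the
  interpolated crossing of `rest + 0.1 × amplitude`; cells are pre-paced 100
  beats (stimulus −52 pA/pF, 1 ms; tissue −40 µA/cm², 3 ms).
* **Dynamic restitution** — 30 beats per cycle length, 1000→400 ms in 50-ms
  then 10-ms decrements until 1:1 capture fails; DI = PCL − previous APD;
  maximum slope by centered finite differences, no smoothing.
* **S1–S2 restitution** — 30 S1 at PCL 1000 ms, one S2 at the programmed DI
  after the last S1's APD90; failed captures are missing points.
* **Afterdepolarizations** — positive deflections (≥1 mV prominence)
  between the 50% and 90% repolarization instants are EADs, between 90%
  repolarization and the next stimulus DADs.  The Ito spike-notch-dome falls
  before APD50 and is therefore never flagged.
* **Conduction velocity** — `2Δx/Δt` between probes at 1/4 and 3/4 of the
  homogeneous MCELL cable, activation = maximum dVm/dt (tracked at full
  resolution during the run).
* **MPCL** — descending 1-ms scan from PCL 400 ms; per trial a 10-beat S1
  train on the 60/45/60 transmural cable, distal capture classified over the
  last 5 beats; the largest PCL classified 2:1 is reported.
* **Pseudo-ECG** — discretized Gima–Rudy line integral
  `φe ∝ Σ (−∂Vm/∂x) ∂(1/r)/∂x dx`.  The electrode sits on the cable axis
  20 mm beyond the **ENDO** end: with TP06's nearly equal ENDO and EPI APDs
  the repolarization sequence runs ENDO→M→EPI-side, and only an ENDO-side
  electrode yields the upright T wave the study describes (an EPI-side
  electrode, the common convention for wedge preparations whose epicardial
  APD is much shorter, inverts the T wave here).  The amplitude scale is
  fixed at 9 mm², which puts the wild-type T peak at ~1 mV; every time-based
  biomarker is invariant to it.
* **QT / T-wave end** — Q onset is the first |φe| excursion above 2% of the
  R peak; the T end is the interpolated intersection of the T downslope with
  the baseline.  The discrete cable retains a small standing diastolic
  offset (diastolic potentials differ slightly across cell classes), so the
  intersection is read where the wave has fallen to within 0.5% of its
  height above the end-of-beat plateau — the closest numerically robust
  reading of the stated y = 0 rule.  T-wave width is T-peak to T-end.
* **RT (repolarization time)** — the study defines RT verbally as the
  largest APD in the cable, yet its printed wild-type value (363.6 ms)
  matches the latest repolarization *instant* (activation time + APD; ours:
  363.9 ms) rather than the largest bare APD (ours: 325.9 ms).  We therefore
  report RT as the latest repolarization instant and also expose the largest
  bare APD (`apd_max`) on the profile object.  DOR stays max−min APD, and
  matches the printed values closely under that reading.
* **Membrane-potential heterogeneity δ** — computed from single-cell traces
  aligned on the stimulus (as the study's cell-pair figures do), not from
  coupled cable nodes.

## Numerics

Voltage-dependent gate steady states, Rush–Larsen factors
(`1 − exp(−dt/τ)`) and current coefficients are pre-tabulated on a 0.02-mV
grid over [−100, +80] mV and linearly interpolated; calcium-dependent terms
are evaluated exactly every step.  Gates use the Rush–Larsen exponential
update (a plain-Euler switch exists on the single-step API; both satisfy the
dt-halving first-order check).  Concentrations and Vm use forward Euler.
The CFL-type bound `D·dt/dx² < 1/2` is enforced before any allocation
(0.0342 for the transmural grid, 0.0493 for the 2D MCELL grid).  The
explicit stencil keeps a contiguous Vm copy so the 2D Laplacian does not
stride through the per-node state rows.  Double precision throughout; the
pipeline contains no random number generation, so re-runs are bit-identical
on one platform.

Two discrete-scheme properties worth knowing: (i) at the study grid the
upstroke spans only a few nodes, so the first-order scheme carries ~8%
numerical dispersion — halving dx raises CV from 0.340 to 0.367 mm/ms.  The
printed study CV (0.344) is itself a dx = 0.15 mm value, so the package
reports CV at that grid; the sqrt(D) scaling law is exact only when dx is
scaled with sqrt(D) (self-similar refinement).  (ii) mirror-ghost Neumann
boundaries conserve the half-weighted boundary sum of Vm (the finite-volume
reading of the stencil), which is the invariant the tests assert.

## Synthetic fixtures

`runner_fixtures.generate_synthetic_trace` builds piecewise-linear AP trains
(instant rise, flat plateau, linear ramp, optional triangular bump) whose
APD90 (`plateau + 0.9·ramp`), amplitude and event placement follow in closed
form, so every measurement operation is tested without the solver.  These
fixtures emulate only the waveform geometry that the measurements consume —
not upstroke shape, rate adaptation or calcium dynamics — so passing
fixture tests validates the *measurement* code, while the biological claims
rest on the simulated protocols.

## Desk-scale 2D substitutes

The full-size sheet experiments are far larger than a one-CPU test budget
allows, so the 2D tests run reduced domains and assert the qualitative
outcomes:

* **Vulnerability** — a 24.75 × 18–30 mm transmural sheet (full-size is
  24.75 × 150 mm), stimulus strip along half the lateral extent of the ENDO
  edge but aligned to one lateral border, which preserves the full reentry
  path length on the other side.  Two stimuli at S1–S1 = 350 ms: the second
  wave reaches the midmyocardial layer ~37 ms after the stimulus, after the
  wild-type tissue's latest repolarization (~364 ms) but before R858H's
  (~403 ms), so WT conducts bidirectionally while R858H blocks
  unidirectionally and re-excites around the recovered lateral edge.  In our
  model the R858H block window closes at S1–S1 ≈ 365 ms — coincidentally
  the study's own full-size reentry threshold for this allele.
* **Spiral** — cross-field S1–S2 on a homogeneous MCELL sheet
  (D = 0.154 mm²/ms, dx = 0.25 mm) at 35 mm instead of 375 mm; the S2
  fires when the S1 repolarization tail clears the midline (−70 mV at the
  centre probe; a configurable offset explores the vulnerable window).
  The rotor-tip excursion in this medium (CV × period / 2π ≈ 38 mm)
  exceeds any desk-scale domain, so the break cannot complete a rotation
  here: the dominant-frequency check against the full-size value is
  expected to fail at this scale, and a sustained rotor needs a sheet of
  roughly 120 mm or more per side.

## Known residuals and limitations

With the supplementary variant/SR constants unavailable, the calibrated
dialect reproduces calcium biomarkers, CV, DOR, RT and the
afterdepolarization phenotype well, but three quantity families retain
systematic offsets that we report rather than tune away:

* single-cell APDs are 1–3% long for the extreme alleles (WT +3.8 ms,
  R858H +7.4 ms at PCL 1,000 ms);
* the dynamic-restitution maximum slopes are flatter than reported
  (R858H ENDO ~1.1 vs 1.35; MCELL ~1.1–1.3 vs 2), and consequently the
  MPCL block thresholds sit ~8–15% below the printed values (R858H 340 vs
  370 ms, WT 300 vs 352 ms) — the steepness of restitution at short
  diastolic intervals is the dominant unknown of the missing supplementary
  formulation;
* the pseudo-ECG T wave peaks earlier and broader than printed (QT ~6%
  short, T width wide), which follows from the flatter transmural APD
  profile on the EPI side;
* the desk-scale spiral cannot rotate (above), so its dominant-frequency
  read-out does not reach the full-size 2.8 Hz value.

Further limitations: no Markov channel models, no calcium-spark spatial
structure, no β-adrenergic signalling, isotropic diffusion only, and no 3D
anatomical geometry — all outside this package's scope.
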