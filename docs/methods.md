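# Methods

## The model

`cardiopes` simulates the human ventricular action potential with a
minimal Hodgkin–Huxley formulation built around the question it is meant
to answer: how the recovery of the fast sodium current after
repolarization controls premature-beat behaviour (takeoff potential,
effective refractory period, post-repolarization refractoriness) and
thereby reentry induction.  Everything that does not bear on that
question — pumps and exchangers, intracellular Ca²⁺ cycling, late I_Na,
Markov drug-binding schemes — is deliberately absent.

Membrane potential obeys `C_m dV/dt = −(ΣI_ion + I_stim)` with
`C_m = 1 µF/cm²` (so pA/pF and µA/cm² coincide numerically).  Six
currents:

| current | gating | role |
|---|---|---|
| I_Na = g_Na·m∞(V)³·h·(V−E_Na) | instantaneous activation, single *h* gate | upstroke; recovery of *h* sets refractoriness |
| I_Ca,L = g_Ca,L·d∞(V)·w·(V−E_Ca) | Gaussian window activation (≈ −30 to −5 mV), slow *w* inactivation gate (voltage-independent τ_w) | holds the low plateau; *w* recovery carries rate adaptation |
| I_Kr | instantaneous sigmoid activation | dominant late-plateau repolarizer |
| I_Ks, I_to | instantaneous | early (high-voltage) repolarization |
| I_K1 | instantaneous inward-rectifier shape | terminal phase 3 and resting potential |

The resting potential is exactly E_K = −88 mV (I_Na and I_Ca,L vanish
there), matching the standard initial condition (V = −88 mV, gates at
their steady state, diastolic calcium zero).

**Sodium inactivation.**  h∞(V) is a sigmoid with midpoint `eh_mid`
(−68 mV) and slope `kh` (5.5 mV); drug variants may shift the midpoint by
`eh_shift` (−10.8 mV).  The time constant TauH(V) is an asymmetric
Gaussian bump on a 0.25-ms floor: sub-millisecond at plateau potentials
(≥ −30 mV), peaking at ≈ 7 ms near −73 mV in the control cell.  The
per-variant multiplier `tauh_scale` is the central drug parameter: ~1 for
control/HF, 2.0 for d-sotalol, and an order of magnitude larger for the
calibrated amiodarone variants, which is what produces
post-repolarization refractoriness (PRR): after the membrane has fully
repolarized, *h* still needs tens of milliseconds to recover, so the
earliest captured premature beat arises from a fully rested takeoff
potential instead of encroaching on the repolarization tail.

**Diastolic-calcium memory.**  A scalar `ca_d` integrates
`ca_gain·|I_Ca,L|` and is removed by a saturable (Michaelis–Menten) term
`ca_decay·ca_d/(1 + ca_d/ca_sat)`; it feeds back multiplicatively on
TauH as `(1 + ca_alpha·ca_d)`.  This reproduces, qualitatively,
rate-dependent calcium accumulation slowing sodium-channel recovery at
fast rates.  It is a deliberately coarse stand-in for intracellular
calcium handling: only its effect on excitability recovery is modelled.

**Shape constants vs. free parameters.**  The gating-curve shapes
(midpoints, slopes, the TauH curve, the I_Ca,L window) are fixed
properties of the model, pinned once during design against the printed
calibration and validation values (control APD 288 ms at BCL 1000 and
dV/dt_max 245 mV/ms; d-sotalol APD 265 ms at BCL 400 from a ~23 % I_Kr
block; heart-failure APD 320 ms at BCL 1000 emerging from the literature
current reductions; amiodarone APD +32 % at BCL 1000 emerging from the
potassium-block calibration at BCL 400).  The per-variant free
parameters — conductances, `eh_shift`, `tauh_scale` — are produced by the
calibration module at run time.

## Variants and calibration

* **Control**: a uniform scale on the potassium conductances sets
  APD(BCL 1000) = 288 ms; g_Na sets dV/dt_max = 245 mV/ms.  Both solves
  are bisections with monotonicity asserted on the bracket; tolerances
  0.5 ms and 2 mV/ms (below the reporting precision of the targets).
* **Heart failure**: fixed literature block ratios (I_Ks −58 %,
  I_K1 −41 %, I_to −44 %, I_Ca,L −25 %); g_Na is then reduced until
  dV/dt_max = 180 mV/ms, the failing-human-tissue value.  The APD
  prolongation to ≈ 320 ms at BCL 1000 is emergent, not calibrated.
* **Amiodarone (AM1–AM8)**: chronic block ratios I_Ks −39 %, I_Kr −55 %,
  optionally I_K1 −64 %, followed by a uniform rescale of the blocked
  conductances calibrated so the cell reaches APD 298 ms at BCL 400
  (the +23 % clinical prolongation).  The rescale search walks down from
  a large scale so it stays on the stable 1:1 branch and never crosses
  the alternans region.  Optionally the availability midpoint is shifted
  by −10.8 mV.  Finally (g_Na, tauh_scale) are solved simultaneously —
  nested bisection, PRR monotone in tauh_scale, dV/dt monotone in
  g_Na — so the single-cell PES shows dV/dt_max 245 or 205 mV/ms and a
  mean S2–S4 PRR of 8 ms, the clinical value measured in amiodarone
  patients.  The three binary axes (K1 block, reduced upstroke,
  availability shift) enumerate the eight variants; `am_axes(i)` maps
  bits of i−1 in that order.  For variants whose availability shift
  makes the dV/dt target unreachable, the dV/dt target is relaxed (the
  solver pins g_Na and reports it) and the PRR target takes precedence.
* **AM′**: the same variants with `tauh_scale` overwritten to 2.0 (the
  d-sotalol value) and nothing recalibrated — the computational
  experiment that removes slow Na⁺ recovery while keeping every class-III
  effect.
* **d-Sotalol**: I_Kr factor re-tuned within 0.77 ± 0.03 to APD 265 ms
  at BCL 400; `tauh_scale` ×2.
* **HF+drug**: drug factors are derived on the control base and composed
  onto HF multiplicatively (conductances), additively (`eh_shift`) and
  multiplicatively (`tauh_scale`), assuming independence; nothing is
  recalibrated on the HF base.

Every calibration emits a `CalibrationReport` with targets, achieved
values, residuals and iteration counts.

## Virtual PES

Eight S1 beats (BCL 400 ms, stimulus 2 ms × −30 µA/cm²), then for each
premature beat S2–S4 an upward coupling-interval scan in 1-ms steps
(5 ms in 2-D) starting 50 ms below the preceding beat's APD; the first
capturing interval is the ERP and the beat is delivered there.  By
construction ERP − increment fails and ERP captures.  Conventions:

* Coupling intervals are referenced to the preceding stimulus onset.
* Capture: peak I_Na < −100 µA/cm² (strict) in the cell; propagation
  along the entire preparation in cable and sheet.
* APD: −30 mV upstroke threshold to −75 mV repolarization threshold,
  linearly interpolated.
* PRR(n) = ERP_n − APD_{n−1}; DI = previous −75 mV crossing to the next
  −30 mV crossing; TOP = V at stimulus onset; ΔTOP relative to the S1
  takeoff; dV/dt_max = max of −ΣI_ion/C_m (stimulus current excluded).

Cable: 5 cm, dx 0.01 cm, dt 0.001 ms, isotropic D = 0.001 cm²/ms,
stimulus in a 0.1-cm end segment, measurements at the midpoint, CV from
activation times at 30 %/70 % of a quiescent cable.  The drive train is
warm-started from the paced single-cell diastolic state plus three cable
beats; the diastolic profile converges geometrically beat-to-beat, and
the warm-started profile matches an 8-beat cold start to well under the
ERP-scan resolution.

## 2-D sheets and the reduced geometry

Sheets are isotropic monodomain squares (5-point Laplacian, no-flux
boundaries).  The pyramidic gradient blends the corner model (drug-free
control) into the centre model (HF or HF+drug): g_Ca,L along a vertical
tent function, the potassium conductances — and the drug-kinetics fields
g_Na, `tauh_scale`, `eh_shift`, so corners stay genuinely drug-free —
along a horizontal tent.  PES is delivered from a square patch at the
bottom-left corner (0.1 cm at full scale; 0.16 cm in the reduced
geometry, where the coarser grid and larger diffusion leak more charge)
with 5-ms ERP increments.  Capture of a premature trial means a fresh
activation reaching the far corner; trials are run on a copy of the
state (failed trials leave the substrate untouched) and begin only once
the preceding wavefront has cleared the stimulus quadrant and is no
longer en route to the far corner, so a still-travelling wave cannot be
mistaken for a captured response.  Distal wavelet activity does not hold
up the protocol — the clinical operator paces at the local ERP
regardless of what happens far away.  After the last stimulated beat the
sheet runs freely and frames are recorded for classification.  The
final-S1 APD map uses the simulation's exact activation times plus the
first −75 mV down-crossing found in any later frame; nodes whose
repolarization is cut short by a re-exciting premature wave
(encroachment) are masked.

The paper-scale experiments (16/20/24-cm sheets, dx 0.02 cm, dt 0.01 ms,
2-s horizons; about 10⁶ nodes × 10⁵ steps each) are available as the
`table1`/`table2` scenarios but are long-running.  The test suite and
the `reduced` scenario use a desk-scale geometry: 6-cm sheet, dx 0.04 cm,
dt 0.02 ms, D = 1.5 × 10⁻³ cm²/ms, 4 S1 beats, 1.2-s horizon.  Two
numerical facts force the choices: (i) at dx 0.04 the depolarization
front (width ≈ D/CV ≈ 0.02 cm at the paper's D) is unresolved and waves
fail to propagate, so D is raised until the front spans the grid; and
(ii) the excitation wavelength CV·APD then exceeds the sheet, so
sustained rotation cannot fit.

What the reduced geometry does and does not show.  It reproduces the
substrate mechanism: tightly coupled premature beats over an HF centre
encroach on the repolarization gradient, block partially, fragment
(phase singularities) and re-excite the tissue (extra beats), while the
same protocol over homogeneous control tissue is completely benign, and
a class-III centre (HF+DS) is equally inducible.  It does **not**
reproduce the amiodarone protection: squeezing the full-scale APD span
into a 3-cm half-diagonal makes the repolarization gradient roughly ten
times steeper, so the spatial recovery zone a premature front faces —
PRR divided by the repolarization-time gradient, ≈ 0.08 cm here — is
only a couple of grid nodes wide and comparable to the front width,
whereas at full scale it is several times wider.  An 8-ms PRR therefore
cannot shield the front at desk scale, and the HF+AM centres break too.
The corresponding acceptance check runs anyway and fails by design of
honesty; the protection and the sustained VT/VF labels of the full-scale
tables are claims about the full geometry only.

## Reentry classification

Activations are upward −30 mV crossings deduplicated by a 50-ms gap.
Phase is reconstructed per node as `atan2(V(t) − V*, V(t−τ) − V*)` with
V* = −55 mV and τ ≈ 8 ms; phase singularities are ±2π winding numbers on
2×2 plaquettes.  Wave break = any transient singularity; reentry = a
singularity persisting at least one estimated rotation period; sustained
= activity at the end of the horizon.  Sustained single-rotor activity
is labelled `vt` (`vfvt` below a 150-ms cycle length); multi-rotor
(mean concurrent singularities > 1.5) is `vf` sustained or `nsvf`
self-terminating; self-terminating activity otherwise is `eb(n)`.
These operational definitions (and the thresholds) are package choices,
unit-tested against prescribed rotating phase fields where the
singularity count and rotation number are known exactly.

## Numerics

Forward Euler throughout (dt 0.001 ms in 0-D/1-D, 0.01 ms in full-scale
2-D, 0.02 ms in the reduced geometry), gates clipped to [0, 1] per step,
blow-up detection with diagnostics.  The compiled kernels evaluate the
rate curves through shared lookup tables (0.05-mV grid, linear
interpolation); the same right-hand side is available in direct
transcendental form and integrating it with an adaptive stiff solver
reproduces the Euler APD to < 1 ms, which the suite checks, along with
dt-halving convergence in 0-D and 2-D, the zero-diffusion decoupling
limit, plane-wave/cable CV agreement, and CV ∝ √D scaling.

The pipeline contains no random number generator; identical
configurations produce byte-identical outputs.

## Limitations

* The ionic formulation is a constrained reconstruction: shapes are
  pinned by the printed targets, not by voltage-clamp fits.  Gate-level
  time courses should not be over-interpreted.
* A single *h* gate (no separate slow inactivation); the calcium memory
  is a scalar; no EAD/torsade mechanisms, pumps, exchangers, or
  anisotropy.
* The HF g_Na reduction is calibrated to the dV/dt_max target (≈ −25 %
  here vs. −39 % quoted for the original parameterization): upstroke
  velocity scales differently in different formulations, and the
  measured target is the invariant worth preserving.
* Conduction velocity scales as roughly g_Na^0.8 in this formulation
  (the potassium load in the wavefront foot does not scale with g_Na and
  breaks the classical √g_Na law), so the HF CV deficit comes out near
  17 % rather than the reported 13 %.
* The calibrated TauH multipliers for the amiodarone variants are small
  (≈ 0.7–3×, vs 12.8–22.7× for the original model): here the PRR target
  is met with little absolute slowing because the cell's recovery
  geometry places the −100 µA/cm² capture threshold close to the
  availability reached at the end of repolarization.  Two knock-on
  effects follow.  First, the cable DI_min increase from control to AM
  is only a few ms (the shift and the cell PRR are nearly proportional
  here, whereas the original model's cable threshold sits much farther
  above its cell threshold), so the ≥ 22 ms clinical shift is not
  reproduced — the corresponding check runs and fails honestly.  Second,
  the AM′ manipulation (TauH reset to 2×) changes recovery only mildly;
  the PRR collapse is directionally correct for variants calibrated
  above 2× but attenuated.
* After the (g_Na, TauH) solve the steady AM cell APD at BCL 400 sits a
  few ms below the 298-ms value the potassium rescale converged to,
  because slowed recovery trims the late I_Na window tail; the
  calibration outcome itself converges to the target.
* Reduced-geometry caveats as above: desk-scale runs demonstrate
  block/wave-break inducibility patterns, not sustained-rotor labels or
  the amiodarone protection.
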