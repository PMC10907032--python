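# cardiopes

Virtual programmed electrical stimulation (PES) in minimal human
action-potential models of heart failure and antiarrhythmic drug action.

## The problem

Patients with heart failure (HF) are vulnerable to reentrant ventricular
arrhythmias triggered by tightly coupled premature beats: a premature
wavefront that encroaches on the repolarization tail of the previous
wave has a depressed takeoff potential (TOP), a slow upstroke, and slow
conduction — the classic substrate for wave break and reentry.  Chronic
amiodarone prevents these arrhythmias, but it is both a class III drug
(potassium-channel block, APD prolongation) and a class I drug
(sodium-channel modification).  Which property protects?

`cardiopes` implements a family of minimal ventricular cell models —
control, HF, eight chronic-amiodarone variants (AM1–AM8), a pure
class III comparator (d-sotalol), and their HF combinations — each
calibrated to printed human/clinical measurements, and subjects them to
the clinical S1–S4 extrastimulus protocol in single cells, 1-D cables,
and 2-D tissue sheets carrying APD gradients.  The central quantity is
**post-repolarization refractoriness**, PRR = ERP − APD: when the
recovery time constant of sodium-channel inactivation (TauH) is slowed,
excitability returns only *after* full repolarization, premature beats
arise from rested tissue (ΔTOP ≈ 0), and the wave front–tail
interactions that seed reentry never occur.  Removing only that slowing
(the AM′ variants, TauH ×2 as for d-sotalol) restores inducibility —
isolating the class I effect as the protective mechanism.

## The model in brief

Six Hodgkin–Huxley currents (I_Na, I_Ca,L, I_Kr, I_Ks, I_K1, I_to) with
mostly instantaneous gating; a single Na⁺ inactivation gate *h* with a
voltage-dependent time constant TauH(V) (< 1 ms in the plateau, ≈ 7 ms
near −73 mV in control, scaled per variant); an I_Ca,L inactivation gate
*w* (voltage-independent τ_w) that carries APD rate adaptation; and a
scalar diastolic-calcium memory that slows Na⁺ recovery at fast rates.
Tissue is isotropic monodomain, forward Euler (dt = 0.001 ms in 0-D/1-D,
0.01 ms in 2-D; dx = 0.01/0.02 cm; D = 0.001 cm²/ms).  See
`docs/methods.md` for the full account, calibration procedure, and
limitations.

## Worked example

```python
from cardiopes import variants, pes, calibrate

reg = variants.VariantRegistry()       # calibrations run on first access
ctl = reg.get("control")               # calibrated baseline
hf  = reg.get("hf")                    # heart-failure remodeling
am3 = reg.get("am3")                   # amiodarone variant (reduced upstroke)

print(round(calibrate.cell_apd(ctl, 1000.0), 1))   # 287.9  (ms; target 288)
print(round(calibrate.cell_apd(hf, 1000.0), 1))    # 319.6  (emergent, +11 %)
print(round(calibrate.cell_dvdt(hf, 400.0), 1))    # 180.0  (failing-tissue
                                                   #         upstroke target)

res = pes.run_pes_cell(am3)            # S1-S4 extrastimulus protocol
print(round(res.mean_prr, 2))          # 8.26   (ms; clinical target ~8)
print(round(res.beat("S1").dvdt_max))  # 205    (mV/ms, reduced-upstroke axis)

res_hf = pes.run_pes_cell(hf)
print(round(res_hf.mean_prr, 2))       # 3.43   (HF: refractoriness glued
                                       #         to the APD)
```

The numbers mean: HF prolongs the action potential but barely moves the
refractory period past it, so tightly coupled premature beats still
encroach on repolarization; the calibrated amiodarone variants show
~8 ms of post-repolarization refractoriness on every premature beat, so
the earliest captured beat arises after full repolarization.

The same protocol runs in tissue:

```python
from cardiopes import scenarios
geo = dict(scenarios.REDUCED_SHEET)
row = scenarios.run_sheet_case(reg, "hf", geo.pop("length"), geo,
                               n_s1=4, horizon=1200.0)
print(row["label"], row["wave_break"], row["extra_beats"])
# nsvf True 4   — premature beats break and re-excite over an HF centre;
# the same protocol over homogeneous control tissue prints none False 0.
# (At this desk scale the HF+AM centres also break; the amiodarone
# protection is a full-scale phenomenon — see docs/methods.md.)
```

A command-line interface wraps the library:

```
cardiopes calibrate -v control -v hf -v am3
cardiopes pes -v am3 --context cell
cardiopes sheet --scenario reduced -v hf -v hf+am3
cardiopes fixtures spiral_synthetic
```

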