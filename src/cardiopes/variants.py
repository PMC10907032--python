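"""Model-variant construction: control, heart failure, amiodarone (AM1–AM8
and the AM′ family), d-sotalol, and multiplicative HF+drug combinations.

Variant semantics
-----------------

* **Control** — the calibrated baseline human cell (APD 288 ms at BCL
  1000 ms, dV/dt_max 245 mV/ms).
* **HF** — heart-failure remodeling: peak I_Ks −58 %, I_K1 −41 %,
  I_to −44 %, I_Ca,L −25 %; g_Na reduced to match the dV/dt_max of
  180 mV/ms measured in failing human tissue.
* **AM1–AM8** — chronic amiodarone, eight variants spanning three binary
  axes (see :func:`am_axes`):  potassium block ratios I_Ks −39 %,
  I_Kr −55 % (and I_K1 −64 % on the k1-block axis) followed by a uniform
  calibrated rescale to APD 298 ms at BCL 400; optionally a −10.8 mV
  availability-curve shift; and (g_Na, tauh_scale) calibrated
  simultaneously to dV/dt_max (205 mV/ms, or 245 if unaltered) and a mean
  S2–S4 PRR of ~8 ms.
* **AM′ (am1p…am8p)** — the same AM variants with the slowed Na⁺-recovery
  removed: tauh_scale overwritten to 2.0 (the d-sotalol value) with *no*
  recalibration.
* **DS** — d-sotalol: I_Kr reduced ~23 % (residually re-tuned within ±3
  points to APD 265 ms at BCL 400) and tauh_scale ×2.0.
* **HF+drug** — effects assumed independent: conductance factors multiply,
  the availability shift adds, tauh_scale multiplies.  Drug factors are
  derived on the control base and composed onto HF without recalibration.

The AM1–AM8 ↔ axes mapping used here (a fixed package convention):
``i-1`` in binary with bits (k1_block, dvdt_reduced, avail_shift), i.e.
AM1 = no-K1-block / dV/dt unaltered / no shift, AM8 = all three applied.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import calibrate
from .params import ModelParams

# Literature block ratios (fractions retained)
HF_FACTORS = {"g_ks": 0.42, "g_k1": 0.59, "g_to": 0.56, "g_cal": 0.75}
AM_K_RATIOS = {"g_ks": 0.61, "g_kr": 0.45}
AM_K1_RATIO = 0.36
AM_AVAIL_SHIFT = -10.8
DS_KR_NOMINAL = 0.77
DS_TAUH_FACTOR = 2.0

# Calibration targets
HF_DVDT_TARGET = 180.0
AM_APD_TARGET = 298.0
AM_PRR_TARGET = 8.0
DVDT_CONTROL = 245.0
DVDT_REDUCED = 205.0
DS_APD_TARGET = 265.0

#: Calibrated control parameterization (cell APD 288 ms @ BCL 1000,
#: dV/dt_max 245 mV/ms @ BCL 400; reproducible via calibrate_control).
CONTROL = ModelParams(
    g_na=3.6254, g_cal=0.06268, g_kr=0.020868, g_ks=0.009143,
    g_k1=0.25870, g_to=0.110209, tau_w=210.77, label="control",
)


@dataclass(frozen=True)
class VariantSpec:
    """Symbolic description of a variant before parameterization."""

    base: str = "control"            # "control" | "hf"
    drug: str = "none"               # "none" | "am" | "am_prime" | "ds"
    am_axes: tuple[bool, bool, bool] = (False, False, False)
    label: str = ""


def am_axes(index: int) -> tuple[bool, bool, bool]:
    """(k1_block, dvdt_reduced, avail_shift) for AM variant ``index`` (1–8)."""
    if not 1 <= index <= 8:
        raise ValueError("AM variant index must be 1..8")
    b = index - 1
    return (bool(b & 4), bool(b & 2), bool(b & 1))


def make_control() -> ModelParams:
    """The calibrated control parameterization."""
    return CONTROL


def apply_hf(p: ModelParams, g_na_factor: float | None = None) -> ModelParams:
    """Heart-failure remodeling of a control-like parameter set.

    The potassium/calcium reductions are fixed literature ratios; g_Na is
    reduced to match dV/dt_max = 180 mV/ms (solved by calibration unless an
    explicit factor is supplied).
    """
    q = p.replace(label=_compose_label(p.label, "hf"),
                  **{k: getattr(p, k) * f for k, f in HF_FACTORS.items()})
    if g_na_factor is not None:
        return q.replace(g_na=p.g_na * g_na_factor)
    g, _, _ = calibrate.calibrate_gna(q, HF_DVDT_TARGET)
    return q.replace(g_na=g)


def apply_am(p: ModelParams,
             axes: tuple[bool, bool, bool],
             k_scale: float | None = None,
             g_na: float | None = None,
             tauh_scale: float | None = None) -> ModelParams:
    """Amiodarone effects on a control-like or HF parameter set.

    Applies the potassium block ratios, the uniform calibrated rescale to
    the APD target, the optional availability shift, and the simultaneous
    (g_Na, tauh_scale) calibration to the dV/dt_max and PRR targets.
    Pre-solved values may be passed to skip the calibrations.
    """
    k1_block, dvdt_reduced, avail_shift = axes
    scaled = ("g_kr", "g_ks", "g_k1") if k1_block else ("g_kr", "g_ks")
    q = p.replace(**{k: getattr(p, k) * f for k, f in AM_K_RATIOS.items()})
    if k1_block:
        q = q.replace(g_k1=q.g_k1 * AM_K1_RATIO)
    q = q.replace(label=_am_label(axes))
    if k_scale is None:
        k_scale, _ = calibrate.calibrate_k_scale(q, AM_APD_TARGET,
                                                 scaled=scaled)
    q = q.replace(**{k: getattr(q, k) * k_scale for k in scaled})
    if avail_shift:
        q = q.replace(eh_shift=p.eh_shift + AM_AVAIL_SHIFT)
    dvdt_target = DVDT_REDUCED if dvdt_reduced else DVDT_CONTROL
    if g_na is None or tauh_scale is None:
        g_na, tauh_scale, _ = calibrate.calibrate_gna_tauh(q, dvdt_target,
                                                           AM_PRR_TARGET)
    return q.replace(g_na=g_na, tauh_scale=tauh_scale)


def apply_ds(p: ModelParams, kr_factor: float | None = None) -> ModelParams:
    """d-Sotalol: I_Kr reduced ~23 % (residual re-tune to the APD target)
    and TauH doubled."""
    if kr_factor is None:
        kr_factor, _ = calibrate.calibrate_ds_kr(
            p.replace(label="ds"), DS_APD_TARGET, nominal=DS_KR_NOMINAL)
    return p.replace(g_kr=p.g_kr * kr_factor,
                     tauh_scale=p.tauh_scale * DS_TAUH_FACTOR,
                     label=_compose_label(p.label, "ds"))


def apply_tauh_prime(am_params: ModelParams) -> ModelParams:
    """AM′: remove the amiodarone slowing of Na⁺ recovery by overwriting
    tauh_scale with the d-sotalol value 2.0.  Everything else (including
    g_Na) is retained and nothing is recalibrated."""
    return am_params.replace(tauh_scale=2.0,
                             label=am_params.label + "p")


# ---------------------------------------------------------------------------
# Multiplicative composition
# ---------------------------------------------------------------------------

_CONDUCTANCES = ("g_na", "g_cal", "g_kr", "g_ks", "g_k1", "g_to")


def factors_of(variant: ModelParams, base: ModelParams) -> dict:
    """Express a variant as deltas relative to a base: multiplicative
    conductance factors, additive eh_shift, multiplicative tauh_scale."""
    f = {g: getattr(variant, g) / getattr(base, g) if getattr(base, g) != 0
         else 1.0 for g in _CONDUCTANCES}
    f["eh_shift"] = variant.eh_shift - base.eh_shift
    f["tauh_scale"] = variant.tauh_scale / base.tauh_scale
    return f


def apply_factors(p: ModelParams, f: dict, label: str = "") -> ModelParams:
    kw = {g: getattr(p, g) * f[g] for g in _CONDUCTANCES}
    kw["eh_shift"] = p.eh_shift + f["eh_shift"]
    kw["tauh_scale"] = p.tauh_scale * f["tauh_scale"]
    if label:
        kw["label"] = label
    return p.replace(**kw)


def compose_hf_drug(hf_deltas: dict, drug_deltas: dict,
                    base: ModelParams | None = None,
                    label: str = "") -> ModelParams:
    """Combine HF and drug effects assuming independence: conductance
    factors multiply, the availability shift adds, tauh_scale multiplies."""
    base = base or make_control()
    combined = {g: hf_deltas[g] * drug_deltas[g] for g in _CONDUCTANCES}
    combined["eh_shift"] = hf_deltas["eh_shift"] + drug_deltas["eh_shift"]
    combined["tauh_scale"] = hf_deltas["tauh_scale"] * drug_deltas["tauh_scale"]
    return apply_factors(base, combined, label=label)


def _compose_label(base_label: str, suffix: str) -> str:
    if base_label in ("", "unnamed", "control"):
        return suffix
    return f"{base_label}+{suffix}"


def _am_label(axes) -> str:
    idx = 1 + (4 if axes[0] else 0) + (2 if axes[1] else 0) + (1 if axes[2] else 0)
    return f"am{idx}"


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

class VariantRegistry:
    """Lazy, cached construction of every named variant.

    Labels: ``control``, ``hf``, ``ds``, ``am1``…``am8``, ``am1p``…``am8p``
    (the AM′ family), and HF combinations ``hf+am3``, ``hf+ds``,
    ``hf+am3p`` etc.  Calibrations run on first access and are cached for
    the process lifetime.
    """

    def __init__(self, control: ModelParams | None = None):
        self._control = control or make_control()
        self._cache: dict[str, ModelParams] = {"control": self._control}

    def labels(self) -> list[str]:
        out = ["control", "hf", "ds", "hf+ds"]
        out += [f"am{i}" for i in range(1, 9)]
        out += [f"am{i}p" for i in range(1, 9)]
        out += [f"hf+am{i}" for i in range(1, 9)]
        out += [f"hf+am{i}p" for i in range(1, 9)]
        return out

    def get(self, label: str) -> ModelParams:
        label = label.strip().lower()
        if label in self._cache:
            return self._cache[label]
        p = self._build(label)
        self._cache[label] = p
        return p

    def _build(self, label: str) -> ModelParams:
        ctl = self._control
        if label == "hf":
            return apply_hf(ctl)
        if label == "ds":
            return apply_ds(ctl)
        if label.startswith("hf+"):
            drug = self.get(label[3:])
            hf_d = factors_of(self.get("hf"), ctl)
            drug_d = factors_of(drug, ctl)
            return compose_hf_drug(hf_d, drug_d, base=ctl, label=label)
        if label.startswith("am"):
            core = label[2:]
            prime = core.endswith("p")
            if prime:
                core = core[:-1]
            try:
                idx = int(core)
                axes = am_axes(idx)
            except ValueError:
                raise KeyError(f"unknown variant label '{label}'") from None
            am = self.get(f"am{idx}") if prime else apply_am(ctl, axes)
            return apply_tauh_prime(am) if prime else am
        raise KeyError(f"unknown variant label '{label}'")


_default_registry: VariantRegistry | None = None


def get_variant(label: str) -> ModelParams:
    """Fetch a variant from the process-wide default registry."""
    global _default_registry
    if _default_registry is None:
        _default_registry = VariantRegistry()
    return _default_registry.get(label)
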