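"""Domain containers: model parameters, cell state, and instantaneous currents.

All voltages are in mV, times in ms, current densities in µA/cm² and
conductances in mS/cm².  Membrane capacitance is fixed at 1 µF/cm² so that
a stimulus expressed in pA/pF is numerically identical to one in µA/cm².
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

#: membrane capacitance, µF/cm²
C_M = 1.0


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for one action-potential model variant.

    Conductances scale the six membrane currents.  ``eh_mid`` and ``kh``
    locate the steady-state Na⁺ availability curve h∞(V); ``eh_shift`` is an
    additive shift of its midpoint (0 for drug-free variants, −10.8 mV for
    the amiodarone variants that shift availability).  ``tauh_scale``
    multiplies the voltage-dependent Na⁺-inactivation time constant TauH(V)
    (1.0 = control; the calibrated amiodarone variants carry large values,
    the d-sotalol variant carries 2.0).  ``tau_w`` is the voltage-independent
    time constant of the L-type Ca²⁺ inactivation gate *w*, which carries the
    model's rate adaptation (memory).  ``ca_gain``/``ca_decay``/``ca_sat``
    govern the scalar diastolic-calcium memory variable and ``ca_alpha`` its
    feedback on Na⁺ recovery.
    """

    g_na: float
    g_cal: float
    g_kr: float
    g_ks: float
    g_k1: float
    g_to: float
    e_na: float = 65.0
    e_ca: float = 50.0
    e_k: float = -88.0
    eh_mid: float = -68.0
    eh_shift: float = 0.0
    kh: float = 5.5
    tauh_scale: float = 1.0
    tau_w: float = 210.77
    ca_gain: float = 5.0e-4
    ca_decay: float = 2.0e-3
    ca_sat: float = 0.5
    ca_alpha: float = 0.15
    label: str = "unnamed"

    def __post_init__(self) -> None:
        for name in ("g_na", "g_cal", "g_kr", "g_ks", "g_k1", "g_to"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tauh_scale <= 0:
            raise ValueError("tauh_scale must be positive")
        if self.kh <= 0:
            raise ValueError("kh must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class CellState:
    """Instantaneous state of a single cell.

    ``v`` membrane potential (mV); ``h`` Na⁺ inactivation gate; ``w``
    I_Ca,L inactivation gate; ``ca_d`` diastolic-calcium memory variable
    (arbitrary units, ≥ 0); ``t`` absolute time (ms).
    """

    v: float
    h: float
    w: float
    ca_d: float = 0.0
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.h, self.w, self.ca_d], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "CellState":
        return cls(v=float(y[0]), h=float(y[1]), w=float(y[2]),
                   ca_d=float(y[3]), t=t)

    def validate(self) -> None:
        if not np.isfinite(self.v):
            raise FloatingPointError(f"non-finite membrane potential at t={self.t}")
        if not (0.0 <= self.h <= 1.0 and 0.0 <= self.w <= 1.0):
            raise ValueError("gates out of [0, 1]")
        if self.ca_d < 0:
            raise ValueError("ca_d must be non-negative")


@dataclass(frozen=True)
class CurrentSet:
    """The six membrane current densities (µA/cm²; inward negative)."""

    i_na: float
    i_cal: float
    i_kr: float
    i_ks: float
    i_k1: float
    i_to: float

    @property
    def i_total(self) -> float:
        return (self.i_na + self.i_cal + self.i_kr +
                self.i_ks + self.i_k1 + self.i_to)
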