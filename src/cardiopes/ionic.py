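"""Single-cell ionic model.

A minimal Hodgkin–Huxley formulation of the human ventricular action
potential with six membrane currents:

* I_Na   — fast sodium current, instantaneous activation m∞(V)³ and a single
  inactivation gate *h* whose time constant TauH(V) is voltage dependent:
  sub-millisecond during the plateau (so I_Na shuts rapidly after the
  upstroke) and maximal (≈ 7 ms in control) in the phase-3/diastolic range.
  The recovery of *h* during and after repolarization is what sets the
  effective refractory period and, when TauH is slowed by drug action,
  produces post-repolarization refractoriness.
* I_Ca,L — L-type calcium current with instantaneous window-type activation
  d∞(V) (active between roughly −30 and −5 mV) and a slow inactivation gate
  *w* with voltage-independent time constant tau_w.  The slow recovery of
  *w* between beats carries APD rate adaptation.
* I_Kr, I_Ks, I_K1, I_to — potassium currents with instantaneous gating.
  I_Kr dominates late-plateau repolarization, I_K1 the terminal phase-3
  tail and resting potential, I_Ks and I_to the early (high-voltage) part
  of the plateau.

A scalar diastolic-calcium memory variable accumulates with integrated
|I_Ca,L| and is removed by a saturable (Michaelis–Menten) uptake; it feeds
back multiplicatively on TauH, slowing Na⁺ recovery at fast rates.

All gating-curve *shape* constants below are fixed properties of the model;
variant construction only rescales conductances, shifts the availability
midpoint, and scales TauH.  The conductance values of the control
parameterization are produced by :mod:`cardiopes.calibrate` against the
clinical targets (APD, dV/dt_max, PRR).
"""
from __future__ import annotations

import numpy as np

from .params import C_M, CellState, CurrentSet, ModelParams

# ---------------------------------------------------------------------------
# Gating-curve shape constants (model definition, not per-variant knobs)
# ---------------------------------------------------------------------------
#: I_Na activation midpoint / slope (mV)
VM, KM = -45.0, 5.0
#: I_Ca,L window-activation centre / width (mV): Gaussian window, active
#: between roughly -30 and -5 mV
VD, KD = -17.0, 9.0
#: I_Ca,L inactivation-gate steady state midpoint / slope (mV)
VW, KW = -23.591, 6.0
#: I_Kr activation midpoint / slope (mV)
VXR, KXR = -25.252, 10.95
#: I_Ks activation midpoint / slope (mV)
VXS, KXS = -3.23, 3.678
#: I_K1 rectification midpoint / slope (mV)
VK1, KK1 = -73.243, 15.604
#: I_to activation midpoint / slope (mV)
VTO, KTO = 2.0, 9.0
#: TauH(V) baseline curve: plateau floor + asymmetric Gaussian bump peaking
#: near -73 mV (slower fall on the depolarized flank, but still < 1 ms at
#: and above -30 mV)
TAUH_FLOOR, TAUH_AMP, TAUH_V = 0.25, 6.75, -73.0
TAUH_SIG_L, TAUH_SIG_R = 14.0, 28.0

# Lookup-table grid shared by all integrators
V_TAB_MIN, V_TAB_MAX, DV_TAB = -130.0, 90.0, 0.05


def _sig(v, mid, k):
    return 1.0 / (1.0 + np.exp(-(v - mid) / k))


def m_inf(v):
    """Steady-state I_Na activation."""
    return _sig(v, VM, KM)


def h_inf(v, p: ModelParams):
    """Steady-state Na⁺ availability, with the variant's additive shift."""
    mid = p.eh_mid + p.eh_shift
    return 1.0 / (1.0 + np.exp((v - mid) / p.kh))


def tau_h0(v):
    """Baseline voltage-dependent Na⁺ inactivation time constant (ms)."""
    v = np.asarray(v, dtype=float)
    sig = np.where(v < TAUH_V, TAUH_SIG_L, TAUH_SIG_R)
    return TAUH_FLOOR + TAUH_AMP * np.exp(-(((v - TAUH_V) / sig) ** 2))


def tau_h(v, p: ModelParams, ca_d: float = 0.0):
    """TauH(V) for a variant: baseline curve × tauh_scale × calcium feedback."""
    return p.tauh_scale * (1.0 + p.ca_alpha * ca_d) * tau_h0(v)


def d_inf(v):
    """I_Ca,L window activation (Gaussian in V)."""
    v = np.asarray(v, dtype=float)
    return np.exp(-(((v - VD) / KD) ** 2))


def w_inf(v):
    """Steady-state of the I_Ca,L inactivation gate."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - VW) / KW))


def xr_inf(v):
    return _sig(np.asarray(v, dtype=float), VXR, KXR)


def xs_inf(v):
    return _sig(np.asarray(v, dtype=float), VXS, KXS)


def k1_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v - VK1) / KK1))


def r_inf(v):
    return _sig(np.asarray(v, dtype=float), VTO, KTO)


# ---------------------------------------------------------------------------
# Currents and right-hand side
# ---------------------------------------------------------------------------

def ionic_currents(state: CellState, p: ModelParams) -> CurrentSet:
    """Instantaneous membrane currents for a cell state (inward negative)."""
    v, h, w = state.v, state.h, state.w
    return CurrentSet(
        i_na=p.g_na * float(m_inf(v)) ** 3 * h * (v - p.e_na),
        i_cal=p.g_cal * float(d_inf(v)) * w * (v - p.e_ca),
        i_kr=p.g_kr * float(xr_inf(v)) * (v - p.e_k),
        i_ks=p.g_ks * float(xs_inf(v)) * (v - p.e_k),
        i_k1=p.g_k1 * float(k1_inf(v)) * (v - p.e_k),
        i_to=p.g_to * float(r_inf(v)) * (v - p.e_k),
    )


def rhs(t: float, y: np.ndarray, p: ModelParams, i_stim: float = 0.0) -> np.ndarray:
    """Continuous-time right-hand side dy/dt for y = (v, h, w, ca_d).

    Written with direct transcendental evaluation (no lookup tables) so it
    can serve as the right-hand side for an adaptive reference integrator
    as well as for analysis.
    """
    v, h, w, ca = y
    ina = p.g_na * float(m_inf(v)) ** 3 * h * (v - p.e_na)
    ical = p.g_cal * float(d_inf(v)) * w * (v - p.e_ca)
    ik = ((p.g_kr * float(xr_inf(v)) + p.g_ks * float(xs_inf(v)) +
           p.g_k1 * float(k1_inf(v)) + p.g_to * float(r_inf(v))) * (v - p.e_k))
    dv = -(ina + ical + ik + i_stim) / C_M
    th = p.tauh_scale * (1.0 + p.ca_alpha * ca) * float(tau_h0(v))
    dh = (float(h_inf(v, p)) - h) / th
    dw = (float(w_inf(v)) - w) / p.tau_w
    dca = p.ca_gain * abs(ical) - p.ca_decay * ca / (1.0 + ca / p.ca_sat)
    return np.array([dv, dh, dw, dca])


def initial_state(p: ModelParams) -> CellState:
    """Standard initial conditions: V = −88 mV, gates at steady state there,
    diastolic calcium zero."""
    v0 = -88.0
    return CellState(v=v0, h=float(h_inf(v0, p)), w=float(w_inf(v0)),
                     ca_d=0.0, t=0.0)


def step_cell(state: CellState, p: ModelParams, i_stim: float = 0.0,
              dt: float = 0.001) -> CellState:
    """One forward-Euler step (reference implementation; the production
    integrators in :mod:`cardiopes._kernels` are table-based and compiled).

    Gates are clipped to [0, 1] after the update to guard forward-Euler
    overshoot.  Raises on numerical blow-up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = state.as_array()
    dy = rhs(state.t, y, p, i_stim)
    y = y + dt * dy
    if not np.all(np.isfinite(y)):
        bad = ("v", "h", "w", "ca_d")[int(np.argmax(~np.isfinite(y)))]
        raise FloatingPointError(
            f"numerical blow-up in {bad} at t={state.t + dt:.4f} ms")
    y[1] = min(max(y[1], 0.0), 1.0)
    y[2] = min(max(y[2], 0.0), 1.0)
    y[3] = max(y[3], 0.0)
    return CellState.from_array(y, t=state.t + dt)


# ---------------------------------------------------------------------------
# Lookup tables for the compiled integrators
# ---------------------------------------------------------------------------

def build_tables(p: ModelParams) -> np.ndarray:
    """Voltage lookup tables used by the compiled kernels.

    Returns an array of shape (9, n) over the grid
    [V_TAB_MIN, V_TAB_MAX] with spacing DV_TAB:

    0: m∞³(V)·(V−E_Na)        (multiply by g_na·h)
    1: d∞(V)·(V−E_Ca)         (multiply by g_cal·w)
    2: xr∞(V)·(V−E_K)         (multiply by g_kr)
    3: xs∞(V)·(V−E_K)         (multiply by g_ks)
    4: k1∞(V)·(V−E_K)         (multiply by g_k1)
    5: r∞(V)·(V−E_K)          (multiply by g_to)
    6: h∞(V) at eh_shift = 0  (looked up at V − eh_shift)
    7: TauH₀(V)
    8: w∞(V)

    The tables depend only on gating-curve shapes and reversal potentials,
    which are shared across variants; conductances, tauh_scale and eh_shift
    are applied per cell (or per tissue node) by the kernels.
    """
    v = np.arange(V_TAB_MIN, V_TAB_MAX + DV_TAB / 2, DV_TAB)
    tabs = np.empty((9, v.size))
    tabs[0] = m_inf(v) ** 3 * (v - p.e_na)
    tabs[1] = d_inf(v) * (v - p.e_ca)
    tabs[2] = xr_inf(v) * (v - p.e_k)
    tabs[3] = xs_inf(v) * (v - p.e_k)
    tabs[4] = k1_inf(v) * (v - p.e_k)
    tabs[5] = r_inf(v) * (v - p.e_k)
    tabs[6] = 1.0 / (1.0 + np.exp((v - p.eh_mid) / p.kh))
    tabs[7] = tau_h0(v)
    tabs[8] = w_inf(v)
    return np.ascontiguousarray(tabs)
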