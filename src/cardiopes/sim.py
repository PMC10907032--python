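"""Drivers around the compiled kernels: traces, pacing, cable runs.

The protocol logic (ERP searches, beat bookkeeping) lives in
:mod:`cardiopes.pes`; this module provides the plain simulation surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, ionic
from .params import CellState, ModelParams

#: default integration step for 0-D and 1-D simulations (ms)
DT_CELL = 0.001
#: default trace recording interval (ms)
REC_MS = 0.05

_TABLE_CACHE: dict = {}


def get_tables(p: ModelParams) -> np.ndarray:
    """Shared voltage lookup tables (cached on the shape-determining fields)."""
    key = (p.e_na, p.e_ca, p.e_k, p.eh_mid, p.kh)
    tabs = _TABLE_CACHE.get(key)
    if tabs is None:
        tabs = ionic.build_tables(p)
        _TABLE_CACHE[key] = tabs
    return tabs


def _pvec(p: ModelParams) -> np.ndarray:
    return np.array([p.g_na, p.g_cal, p.g_kr, p.g_ks, p.g_k1, p.g_to,
                     p.tauh_scale, p.eh_shift])


def _svec(p: ModelParams) -> np.ndarray:
    return np.array([p.tau_w, p.ca_gain, p.ca_decay, p.ca_sat, p.ca_alpha])


@dataclass
class Trace:
    """A recorded voltage/current time course (uniform sampling)."""

    t: np.ndarray
    v: np.ndarray
    i_na: np.ndarray | None = None
    i_cal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def cross_up(self, thr: float) -> np.ndarray:
        """Times of upward crossings of ``thr`` (linear interpolation)."""
        v = self.v
        idx = np.nonzero((v[:-1] < thr) & (v[1:] >= thr))[0]
        if idx.size == 0:
            return np.empty(0)
        frac = (thr - v[idx]) / (v[idx + 1] - v[idx])
        return self.t[idx] + frac * (self.t[idx + 1] - self.t[idx])

    def cross_down(self, thr: float) -> np.ndarray:
        v = self.v
        idx = np.nonzero((v[:-1] >= thr) & (v[1:] < thr))[0]
        if idx.size == 0:
            return np.empty(0)
        frac = (v[idx] - thr) / (v[idx] - v[idx + 1])
        return self.t[idx] + frac * (self.t[idx + 1] - self.t[idx])


def simulate_cell(p: ModelParams, state: CellState, duration: float,
                  stim_onsets=(), stim_amp: float = -30.0,
                  stim_dur: float = 2.0, dt: float = DT_CELL,
                  rec_ms: float = REC_MS, snap_ms: float = 0.0):
    """Integrate one cell for ``duration`` ms from ``state`` (not modified).

    ``stim_onsets`` are stimulus onset times relative to the start of this
    segment.  Returns ``(trace, final_state)``, or
    ``(trace, final_state, snapshots)`` when ``snap_ms`` > 0, where
    ``snapshots[k]`` is the :class:`CellState` at ``k*snap_ms`` ms after
    segment start (restart points for ERP searches).  The trace ``meta``
    holds the ionic ``dvdt_max`` and peak inward ``peak_i_na`` /
    ``peak_i_cal``.  Raises :class:`FloatingPointError` on blow-up.
    """
    tabs = get_tables(p)
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(rec_ms / dt)))
    nrec = (n_steps + rec_every - 1) // rec_every
    v_rec = np.empty(nrec)
    ina_rec = np.empty(nrec)
    ical_rec = np.empty(nrec)
    out = np.empty(3)
    if snap_ms > 0:
        snap_every = max(1, int(round(snap_ms / dt)))
        nsnap = (n_steps + snap_every - 1) // snap_every
        snaps = np.empty((nsnap, 4))
    else:
        snap_every = 0
        snaps = np.empty((0, 4))
    y = state.as_array()
    status = _kernels.cell_run(tabs, _pvec(p), _svec(p), y, dt, n_steps,
                               np.asarray(stim_onsets, dtype=np.float64),
                               stim_amp, stim_dur, rec_every,
                               v_rec, ina_rec, ical_rec, out,
                               snap_every, snaps)
    if status < 0:
        raise FloatingPointError(
            f"numerical blow-up in cell simulation of '{p.label}'")
    t = state.t + np.arange(nrec) * rec_every * dt
    trace = Trace(t=t, v=v_rec, i_na=ina_rec, i_cal=ical_rec,
                  meta={"dvdt_max": out[0], "peak_i_na": out[1],
                        "peak_i_cal": out[2]})
    final = CellState.from_array(y, t=state.t + n_steps * dt)
    if snap_ms > 0:
        states = [CellState.from_array(snaps[k],
                                       t=state.t + k * snap_every * dt)
                  for k in range(snaps.shape[0])]
        return trace, final, states
    return trace, final


def steady_state_pace(p: ModelParams, bcl: float, n_beats: int = 8,
                      stim_amp: float = -30.0, stim_dur: float = 2.0,
                      dt: float = DT_CELL, state: CellState | None = None,
                      rtol: float = 1e-3) -> tuple[Trace, CellState, dict]:
    """Pace a cell at ``bcl`` for ``n_beats``; return the final beat.

    Returns ``(trace, pre_state, info)`` where ``trace`` is the recorded
    V(t) of the final beat, ``pre_state`` the diastolic state immediately
    before its stimulus, and ``info`` reports capture (peak I_Na more
    negative than −100 µA/cm² on the final beat) and whether the diastolic
    values of the last two beats agree to ``rtol`` (0.1 % default).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if state is None:
        state = ionic.initial_state(p)
    prev_dia = None
    dia_converged = False
    trace = None
    pre_state = state
    for b in range(n_beats):
        pre_state = state
        trace, state = simulate_cell(p, state, bcl, stim_onsets=[0.0],
                                     stim_amp=stim_amp, stim_dur=stim_dur,
                                     dt=dt)
        dia = state.as_array()
        if prev_dia is not None:
            denom = np.maximum(np.abs(prev_dia), 1e-8)
            dia_converged = bool(np.all(np.abs(dia - prev_dia) / denom < rtol)
                                 or np.allclose(dia, prev_dia, atol=1e-6))
        prev_dia = dia
    captured = trace.meta["peak_i_na"] < -100.0
    if not captured:
        raise RuntimeError(
            f"no suprathreshold response while pacing '{p.label}' at "
            f"BCL={bcl} ms (peak I_Na {trace.meta['peak_i_na']:.1f} µA/cm²)")
    info = {"captured": captured, "diastole_converged": dia_converged,
            "final_state": state}
    return trace, pre_state, info


# ---------------------------------------------------------------------------
# 1-D cable
# ---------------------------------------------------------------------------

@dataclass
class CableState:
    """State arrays of a uniform cable plus its geometry.

    ``armed`` is the activation-detector latch: a node must repolarize
    below −60 mV before its next −30 mV upstroke counts as an activation.
    """

    v: np.ndarray
    h: np.ndarray
    w: np.ndarray
    ca: np.ndarray
    armed: np.ndarray
    dx: float
    t: float = 0.0

    @property
    def n(self) -> int:
        return self.v.shape[0]

    def copy(self) -> "CableState":
        return CableState(self.v.copy(), self.h.copy(), self.w.copy(),
                          self.ca.copy(), self.armed.copy(), self.dx, self.t)


def cable_initial_state(p: ModelParams, length: float = 5.0,
                        dx: float = 0.01) -> CableState:
    n = int(round(length / dx)) + 1
    s0 = ionic.initial_state(p)
    return CableState(np.full(n, s0.v), np.full(n, s0.h), np.full(n, s0.w),
                      np.zeros(n), np.ones(n, dtype=np.uint8), dx)


def cable_state_from_cell(p: ModelParams, cell: CellState,
                          length: float = 5.0, dx: float = 0.01) -> CableState:
    """Uniform cable state initialised from a (typically paced) cell state."""
    n = int(round(length / dx)) + 1
    armed = np.full(n, 1 if cell.v < -60.0 else 0, dtype=np.uint8)
    return CableState(np.full(n, cell.v), np.full(n, cell.h),
                      np.full(n, cell.w), np.full(n, cell.ca_d), armed, dx)


def simulate_cable(p: ModelParams, cab: CableState, duration: float,
                   stim_onsets=(), stim_amp: float = -30.0,
                   stim_dur: float = 2.0, diffusion: float = 0.001,
                   dt: float = DT_CELL, stim_len: float = 0.1,
                   rec_node: int | None = None, rec_ms: float = REC_MS,
                   far_mode: int = 0, stall_ms: float = 0.0):
    """Integrate a cable in place for up to ``duration`` ms.

    The stimulus is injected into a ``stim_len`` cm segment at node 0.
    Returns ``(trace_at_rec_node, t_act, info)``; ``t_act`` holds absolute
    first-activation (−30 mV upcross) times per node (NaN = never).
    """
    n = cab.n
    if rec_node is None:
        rec_node = n // 2
    tabs = get_tables(p)
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(rec_ms / dt)))
    nrec = (n_steps + rec_every - 1) // rec_every
    v_rec = np.empty(nrec)
    ina_rec = np.empty(nrec)
    t_act = np.full(n, np.nan)
    out = np.empty(2)
    n_stim_nodes = max(1, int(round(stim_len / cab.dx)))
    steps = _kernels.cable_run(tabs, _pvec(p), _svec(p),
                               cab.v, cab.h, cab.w, cab.ca, cab.armed,
                               dt, n_steps,
                               diffusion, cab.dx, n_stim_nodes,
                               np.asarray(stim_onsets, dtype=np.float64),
                               stim_amp, stim_dur, rec_node, rec_every,
                               v_rec, ina_rec, t_act,
                               far_mode, stall_ms, out)
    if steps < 0:
        raise FloatingPointError(
            f"numerical blow-up in cable simulation of '{p.label}'")
    nrec_done = (steps + rec_every - 1) // rec_every
    t = cab.t + np.arange(nrec_done) * rec_every * dt
    trace = Trace(t=t, v=v_rec[:nrec_done], i_na=ina_rec[:nrec_done],
                  meta={"peak_i_na": out[0], "dvdt_max": out[1]})
    t_act = t_act + cab.t
    info = {"steps": steps, "completed": steps == n_steps,
            "far_activated": bool(np.isfinite(t_act[-1]))}
    cab.t += steps * dt
    return trace, t_act, info
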