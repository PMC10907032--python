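"""Virtual programmed electrical stimulation (PES) in cells and cables.

The clinical S1–S4 extrastimulus protocol: eight S1 drive beats at the
basic cycle length, then for each premature beat (S2, S3, S4) the effective
refractory period (ERP) is found by scanning coupling intervals upward in
fixed increments until the stimulus captures; the premature beat is then
delivered at its ERP and the next scan proceeds from it.

Conventions (documented here because the clinical literature varies):

* Coupling intervals and ERPs are referenced to the *stimulus onset* of the
  preceding beat.
* The ERP scan starts 50 ms below the preceding beat's APD (guaranteed
  sub-ERP) and moves upward in ``erp_increment`` steps, so by construction
  ERP − increment fails to capture and ERP captures.
* Capture in a single cell means peak I_Na more negative than
  −100 µA/cm² (strict inequality); capture in tissue means propagation
  along the entire preparation.
* APD is measured between the upward −30 mV crossing and the downward
  −75 mV crossing; PRR for beat *n* is ERP_n − APD_{n−1} (the APD of the
  beat whose repolarization the premature stimulus encroaches on).
* The takeoff potential (TOP) is the membrane potential at stimulus onset;
  ΔTOP is its elevation above the fully rested S1 takeoff.
* dV/dt_max is the maximum ionic (stimulus-free) rate of rise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sim
from .params import CellState, ModelParams
from .sim import CableState, Trace

DEPOL_THR = -30.0
REPOL_THR = -75.0
CAPTURE_INA = -100.0


class ProtocolFailure(RuntimeError):
    """Raised when a PES protocol cannot be completed (e.g. no capture)."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation-protocol settings for PES."""

    bcl: float = 400.0
    n_s1: int = 8
    stim_dur: float = 2.0
    stim_amp: float = -30.0
    erp_increment: float = 1.0
    n_premature: int = 3
    scan_below_apd: float = 50.0
    scan_span: float = 600.0

    def __post_init__(self):
        if self.erp_increment <= 0:
            raise ValueError("erp_increment must be positive")
        if self.stim_amp >= 0:
            raise ValueError("stim_amp must be negative (inward)")


@dataclass
class BeatMeasurement:
    """Per-beat measurements of one PES beat (S1 = last drive beat)."""

    beat: str
    apd: float
    erp: float = float("nan")
    prr: float = float("nan")
    top: float = float("nan")
    d_top: float = float("nan")
    dvdt_max: float = float("nan")
    di: float = float("nan")
    peak_i_na: float = float("nan")
    peak_i_cal: float = float("nan")


@dataclass
class PESResult:
    """Outcome of a full S1–S4 PES run in one preparation."""

    beats: list[BeatMeasurement]
    context: str
    variant: str
    di_min: float = float("nan")
    cv: float = float("nan")

    def beat(self, name: str) -> BeatMeasurement:
        for b in self.beats:
            if b.beat == name:
                return b
        raise KeyError(name)

    @property
    def mean_prr(self) -> float:
        """Mean PRR over the premature beats (S2–S4)."""
        vals = [b.prr for b in self.beats if b.beat != "S1"]
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (beat, metric)."""
        rows = []
        for b in self.beats:
            for metric in ("apd", "erp", "prr", "top", "d_top", "dvdt_max",
                           "di", "peak_i_na", "peak_i_cal"):
                rows.append(dict(variant=self.variant, context=self.context,
                                 beat=b.beat, metric=metric,
                                 value=getattr(b, metric)))
        return pd.DataFrame(rows)


def measure_apd(trace: Trace, depol: float = DEPOL_THR,
                repol: float = REPOL_THR) -> float:
    """APD from the first upward ``depol`` crossing to the next downward
    ``repol`` crossing (linear interpolation between samples)."""
    up = trace.cross_up(depol)
    if up.size == 0:
        raise ValueError("trace never crosses the depolarization threshold")
    dn = trace.cross_down(repol)
    dn = dn[dn > up[0]]
    if dn.size == 0:
        raise ValueError("trace never repolarizes below the threshold")
    return float(dn[0] - up[0])


def capture_test_cell(trace: Trace) -> bool:
    """Cell capture criterion: peak I_Na strictly more negative than
    −100 µA/cm²."""
    peak = trace.meta.get("peak_i_na")
    if peak is None:
        peak = float(np.min(trace.i_na))
    return peak < CAPTURE_INA


def measure_dvdt_max(trace: Trace) -> float:
    """Maximal ionic upstroke velocity of a recorded beat (mV/ms)."""
    if "dvdt_max" in trace.meta:
        return float(trace.meta["dvdt_max"])
    return float(np.max(np.diff(trace.v) / np.diff(trace.t)))


def measure_top(trace: Trace, stim_onset: float) -> float:
    """Takeoff potential: V at the premature stimulus onset."""
    i = int(np.argmin(np.abs(trace.t - stim_onset)))
    return float(trace.v[i])


# ---------------------------------------------------------------------------
# Single-cell PES
# ---------------------------------------------------------------------------

def _chunked_cell_beat(p, state, duration, proto, stim: bool):
    """Simulate one beat segment in a single kernel call, returning
    (trace, snapshots) where snapshots[k] is the state
    ``k * erp_increment`` ms after segment start."""
    onsets = [0.0] if stim else []
    tr, _, snaps = sim.simulate_cell(p, state, duration, stim_onsets=onsets,
                                     stim_amp=proto.stim_amp,
                                     stim_dur=proto.stim_dur,
                                     snap_ms=proto.erp_increment)
    return tr, snaps


def _cell_capture(p, snap_state, proto, window: float = 60.0) -> bool:
    tr, _ = sim.simulate_cell(p, snap_state, window, stim_onsets=[0.0],
                              stim_amp=proto.stim_amp, stim_dur=proto.stim_dur)
    return capture_test_cell(tr)


def run_pes_cell(p: ModelParams, proto: ProtocolSpec = ProtocolSpec(),
                 state: CellState | None = None) -> PESResult:
    """Full S1–S4 PES in a single cell.

    Returns measurements for the final S1 drive beat and each premature
    beat delivered at its ERP.  Raises :class:`ProtocolFailure` if a
    premature beat fails to capture anywhere within the scan span.
    """
    if state is None:
        state = None  # steady_state_pace starts from standard initial state
    # S1 drive train: n_s1 - 1 plain beats, then the final beat free-running
    if proto.n_s1 > 1:
        _, _, info = sim.steady_state_pace(p, proto.bcl, proto.n_s1 - 1,
                                           stim_amp=proto.stim_amp,
                                           stim_dur=proto.stim_dur,
                                           state=state)
        pre = info["final_state"]
    else:
        pre = state or sim.ionic.initial_state(p)
    beats: list[BeatMeasurement] = []
    seg_len = proto.scan_span + 80.0
    trace, snaps = _chunked_cell_beat(p, pre, seg_len, proto, stim=True)
    if not capture_test_cell(trace):
        raise ProtocolFailure(
            f"S1 failed to capture for '{p.label}' "
            f"(peak I_Na {trace.meta['peak_i_na']:.1f})")
    apd = measure_apd(trace)
    top1 = trace.v[0]
    repol_t = float(trace.cross_down(REPOL_THR)[0])
    beats.append(BeatMeasurement(
        beat="S1", apd=apd, top=top1, d_top=0.0,
        dvdt_max=measure_dvdt_max(trace), peak_i_na=trace.meta["peak_i_na"],
        peak_i_cal=trace.meta["peak_i_cal"]))
    prev_apd = apd
    prev_repol = repol_t
    di_min = float("nan")
    for n in range(proto.n_premature):
        name = f"S{n + 2}"
        inc = proto.erp_increment
        # scan starts 50 ms below the previous APD, but never inside the
        # previous beat's own upstroke/stimulus window
        start = max(proto.stim_dur + 8.0, prev_apd - proto.scan_below_apd)
        ci = np.ceil(start / inc) * inc
        erp = None
        while ci <= start + proto.scan_span:
            k = int(round(ci / inc))
            if k >= len(snaps):
                break
            if _cell_capture(p, snaps[k], proto):
                erp = ci
                break
            ci += inc
        if erp is None:
            raise ProtocolFailure(
                f"{name} of '{p.label}': no capture within scan span")
        k = int(round(erp / inc))
        snap = snaps[k]
        trace, snaps = _chunked_cell_beat(p, snap, seg_len, proto, stim=True)
        apd = measure_apd(trace)
        up = float(trace.cross_up(DEPOL_THR)[0])
        di = up - prev_repol
        beats.append(BeatMeasurement(
            beat=name, apd=apd, erp=float(erp), prr=float(erp) - prev_apd,
            top=snap.v, d_top=snap.v - top1,
            dvdt_max=measure_dvdt_max(trace), di=di,
            peak_i_na=trace.meta["peak_i_na"],
            peak_i_cal=trace.meta["peak_i_cal"]))
        if n == 0:
            di_min = di
        prev_apd = apd
        prev_repol = float(trace.cross_down(REPOL_THR)[0])
    return PESResult(beats=beats, context="cell", variant=p.label,
                     di_min=di_min)


# ---------------------------------------------------------------------------
# 1-D cable PES
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CableSpec:
    """Geometry and numerics of the 1-D cable preparation."""

    length: float = 5.0
    dx: float = 0.01
    diffusion: float = 0.001
    dt: float = 0.001
    stim_len: float = 0.1
    #: number of S1 beats actually simulated in the cable after uniform
    #: initialisation from the paced single-cell state (the diastolic state
    #: converges geometrically; see docs/methods.md)
    n_s1_cable: int = 3


def _cable_snapshot_run(p, cab, duration, proto, spec, stim: bool):
    """Run a beat segment saving per-increment snapshots of the full cable."""
    inc = proto.erp_increment
    n_chunks = int(round(duration / inc))
    snaps = [cab.copy()]
    traces = []
    t_act_first = None
    for c in range(n_chunks):
        onsets = [-c * inc] if (stim and c * inc < proto.stim_dur) else []
        tr, t_act, _ = sim.simulate_cable(
            p, cab, inc, stim_onsets=onsets, stim_amp=proto.stim_amp,
            stim_dur=proto.stim_dur, diffusion=spec.diffusion, dt=spec.dt,
            stim_len=spec.stim_len)
        if t_act_first is None:
            t_act_first = t_act
        else:
            m = np.isnan(t_act_first)
            t_act_first[m] = t_act[m]
        traces.append(tr)
        snaps.append(cab.copy())
    t = np.concatenate([tr.t for tr in traces])
    v = np.concatenate([tr.v for tr in traces])
    ina = np.concatenate([tr.i_na for tr in traces])
    meta = {"dvdt_max": max(tr.meta["dvdt_max"] for tr in traces),
            "peak_i_na": min(tr.meta["peak_i_na"] for tr in traces)}
    return Trace(t=t, v=v, i_na=ina, meta=meta), snaps, t_act_first


def _cable_capture(p, snap: CableState, proto, spec, window: float) -> bool:
    """Capture trial: does a stimulus now propagate along the whole cable?"""
    cab = snap.copy()
    _, t_act, info = sim.simulate_cable(
        p, cab, window, stim_onsets=[0.0], stim_amp=proto.stim_amp,
        stim_dur=proto.stim_dur, diffusion=spec.diffusion, dt=spec.dt,
        stim_len=spec.stim_len, far_mode=1, stall_ms=60.0)
    return bool(np.isfinite(t_act[-1]))


def _cable_erp_scan(p, snaps, start, proto, spec, window, coarse=8.0):
    """Upward ERP scan with a coarse pre-pass (failures are cheap, captures
    expensive); returns the shortest capturing coupling interval."""
    inc = proto.erp_increment
    ci = np.ceil(max(inc, start) / inc) * inc
    last_fail = None
    # coarse pass
    while ci <= start + proto.scan_span:
        k = int(round(ci / inc))
        if k >= len(snaps):
            break
        if _cable_capture(p, snaps[k], proto, spec, window):
            fine_lo = ci - coarse if last_fail is not None else ci
            fine = max(np.ceil(max(inc, fine_lo) / inc) * inc,
                       (last_fail + inc) if last_fail is not None else inc)
            while fine <= ci:
                kf = int(round(fine / inc))
                if _cable_capture(p, snaps[kf], proto, spec, window):
                    return float(fine)
                fine += inc
            return float(ci)
        last_fail = ci
        ci += coarse
    return None


def run_pes_cable(p: ModelParams, proto: ProtocolSpec = ProtocolSpec(),
                  spec: CableSpec = CableSpec(),
                  n_premature: int | None = None) -> PESResult:
    """S1–S4 PES in a uniform 1-D cable (stimulus at one end, measurements
    at the cable midpoint).

    The cable is initialised uniformly from the paced single-cell diastolic
    state and driven for ``spec.n_s1_cable`` further S1 beats, which brings
    the diastolic profile to its pacing steady state at a fraction of the
    cost of a full cold-start drive train.
    """
    if n_premature is None:
        n_premature = proto.n_premature
    _, pre_cell, _ = sim.steady_state_pace(p, proto.bcl, proto.n_s1,
                                           stim_amp=proto.stim_amp,
                                           stim_dur=proto.stim_dur)
    cab = sim.cable_state_from_cell(p, pre_cell, spec.length, spec.dx)
    for _ in range(spec.n_s1_cable - 1):
        sim.simulate_cable(p, cab, proto.bcl, stim_onsets=[0.0],
                           stim_amp=proto.stim_amp, stim_dur=proto.stim_dur,
                           diffusion=spec.diffusion, dt=spec.dt,
                           stim_len=spec.stim_len)
    seg_len = proto.scan_span + 80.0
    trace, snaps, t_act = _cable_snapshot_run(p, cab, seg_len, proto, spec,
                                              stim=True)
    if not np.isfinite(t_act[-1]):
        raise ProtocolFailure(
            f"S1 failed to propagate along the cable for '{p.label}'")
    # trial window: S1 traversal time plus margin
    traversal = float(t_act[-1] - t_act[0])
    window = traversal + 150.0
    apd = measure_apd(trace)
    top1 = trace.v[0]
    beats = [BeatMeasurement(
        beat="S1", apd=apd, top=top1, d_top=0.0,
        dvdt_max=measure_dvdt_max(trace),
        peak_i_na=trace.meta["peak_i_na"])]
    prev_apd = apd
    prev_repol = float(trace.cross_down(REPOL_THR)[0])
    di_min = float("nan")
    for n in range(n_premature):
        name = f"S{n + 2}"
        start = max(proto.stim_dur + 8.0, prev_apd - proto.scan_below_apd)
        erp = _cable_erp_scan(p, snaps, start, proto, spec, window)
        if erp is None:
            raise ProtocolFailure(
                f"{name} of '{p.label}': no propagated capture in scan span")
        k = int(round(erp / proto.erp_increment))
        snap = snaps[k]
        if n == n_premature - 1:
            # final premature beat: no further scan, plain run with early stop
            cab2 = snap.copy()
            trace, _, _ = sim.simulate_cable(
                p, cab2, seg_len, stim_onsets=[0.0], stim_amp=proto.stim_amp,
                stim_dur=proto.stim_dur, diffusion=spec.diffusion, dt=spec.dt,
                stim_len=spec.stim_len, far_mode=2)
        else:
            trace, snaps, _ = _cable_snapshot_run(p, snap.copy(), seg_len,
                                                  proto, spec, stim=True)
        apd = measure_apd(trace)
        up = float(trace.cross_up(DEPOL_THR)[0])
        di = up - prev_repol
        beats.append(BeatMeasurement(
            beat=name, apd=apd, erp=float(erp), prr=float(erp) - prev_apd,
            top=float(snap.v[len(snap.v) // 2]),
            d_top=float(snap.v[len(snap.v) // 2]) - top1,
            dvdt_max=measure_dvdt_max(trace), di=di,
            peak_i_na=trace.meta["peak_i_na"]))
        if n == 0:
            di_min = di
        prev_apd = apd
        prev_repol = float(trace.cross_down(REPOL_THR)[0])
    return PESResult(beats=beats, context="cable", variant=p.label,
                     di_min=di_min)


def measure_cv(p: ModelParams, spec: CableSpec = CableSpec(),
               stim_amp: float = -30.0, stim_dur: float = 2.0) -> float:
    """Plane-wave conduction velocity (cm/ms) in a quiescent cable,
    from activation times at 30 % and 70 % of the cable length."""
    cab = sim.cable_initial_state(p, spec.length, spec.dx)
    est_window = spec.length / 0.01 + 100.0
    _, t_act, _ = sim.simulate_cable(
        p, cab, est_window, stim_onsets=[0.0], stim_amp=stim_amp,
        stim_dur=stim_dur, diffusion=spec.diffusion, dt=spec.dt,
        stim_len=spec.stim_len, far_mode=1, stall_ms=100.0)
    n = cab.n
    i1, i2 = int(0.3 * n), int(0.7 * n)
    if not (np.isfinite(t_act[i1]) and np.isfinite(t_act[i2])):
        raise ProtocolFailure(f"conduction failure in CV run for '{p.label}'")
    return float((i2 - i1) * spec.dx / (t_act[i2] - t_act[i1]))
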