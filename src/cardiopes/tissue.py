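"""2-D isotropic monodomain sheets with pyramidic parameter gradients.

The arrhythmia-substrate experiments impose a "pyramidic" heterogeneity on
a square sheet: conductances at the sheet boundary corners equal the
*corner* model (control, or HF for drug studies) and at the sheet centre
equal the *center* model (HF, or HF+drug), with triangular (tent) blends —
g_Ca,L along the vertical axis and the potassium conductances along the
horizontal axis — so the longest APD occurs near the centre of the sheet.
Because every node carries its own parameter mix, one sheet embeds
thousands of distinct cell parameterizations.

Drug kinetic parameters that the drug variants alter (g_Na, tauh_scale,
eh_shift) blend along the same horizontal tent as the potassium
conductances so the corners remain genuinely drug-free.

PES in 2-D: S1 drive from a small square footprint at the bottom-left
corner, then S2–S4 ERP searches at the same site with 5-ms increments;
capture means propagation across the entire sheet.  After the last
stimulated beat the sheet runs freely for a configurable horizon and the
voltage frames are kept for reentry classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, ionic, sim
from .params import CellState, ModelParams
from .pes import DEPOL_THR, REPOL_THR, ProtocolFailure, ProtocolSpec


@dataclass(frozen=True)
class GradientSheetSpec:
    """Geometry, numerics, and the parameter gradient of a sheet."""

    corner_params: ModelParams
    center_params: ModelParams
    length: float = 20.0       # cm
    dx: float = 0.02           # cm
    dt: float = 0.01           # ms
    diffusion: float = 0.001   # cm²/ms
    stim_size: float = 0.1     # cm, square footprint at the corner

    def __post_init__(self):
        n = self.length / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ValueError("length must be an integer multiple of dx")


@dataclass
class TissueField:
    """Grid geometry plus per-node parameter fields (see _kernels.sheet_run)."""

    pf: np.ndarray            # (8, ny, nx) parameter fields
    svec: np.ndarray          # shared scalar parameters
    tabs: np.ndarray          # voltage lookup tables
    spec: GradientSheetSpec
    v: np.ndarray
    h: np.ndarray
    w: np.ndarray
    ca: np.ndarray
    armed: np.ndarray = None  # activation-detector latch (see CableState)
    t: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape

    def state_copy(self):
        return (self.v.copy(), self.h.copy(), self.w.copy(), self.ca.copy(),
                self.armed.copy(), self.t)

    def state_restore(self, snap):
        v, h, w, ca, armed, t = snap
        self.v[:] = v
        self.h[:] = h
        self.w[:] = w
        self.ca[:] = ca
        self.armed[:] = armed
        self.t = t


#: parameter-field order used by the kernels
_FIELD_ORDER = ("g_na", "g_cal", "g_kr", "g_ks", "g_k1", "g_to",
                "tauh_scale", "eh_shift")
#: fields blended along the horizontal (potassium/drug-kinetics) tent
_HORIZONTAL = {"g_kr", "g_ks", "g_k1", "g_to", "g_na", "tauh_scale",
               "eh_shift"}


def build_gradient_sheet(spec: GradientSheetSpec,
                         init: CellState | None = None) -> TissueField:
    """Construct the per-node parameter fields for a pyramidic gradient.

    Vertical tent ``f(y) = 1 − |2y/L − 1|`` blends g_Ca,L; the horizontal
    tent blends the potassium conductances and the drug-kinetics fields.
    The blend fraction is 1 at the sheet centre (centre model) and 0 on the
    boundary (corner model).  Raises if any blended conductance would be
    non-positive.
    """
    a, b = spec.corner_params, spec.center_params
    for f in ("e_na", "e_ca", "e_k", "eh_mid", "kh", "tau_w"):
        if getattr(a, f) != getattr(b, f):
            raise ValueError(f"corner/center params must share '{f}'")
    n = int(round(spec.length / spec.dx)) + 1
    x = np.linspace(0.0, spec.length, n)
    fx = 1.0 - np.abs(2.0 * x / spec.length - 1.0)
    fy = fx.copy()
    FX = np.broadcast_to(fx[None, :], (n, n))
    FY = np.broadcast_to(fy[:, None], (n, n))
    pf = np.empty((8, n, n))
    for k, name in enumerate(_FIELD_ORDER):
        pa, pb = getattr(a, name), getattr(b, name)
        f = FX if name in _HORIZONTAL else FY
        pf[k] = pa + (pb - pa) * f
    for k, name in enumerate(_FIELD_ORDER):
        if name.startswith("g_") and np.any(pf[k] < 0):
            raise ValueError(f"gradient produced negative {name}")
    if np.any(pf[6] <= 0):
        raise ValueError("gradient produced non-positive tauh_scale")
    if init is None:
        init = ionic.initial_state(a)
    fld = TissueField(
        pf=pf, svec=sim._svec(a), tabs=sim.get_tables(a), spec=spec,
        v=np.full((n, n), init.v), h=np.full((n, n), init.h),
        w=np.full((n, n), init.w), ca=np.full((n, n), init.ca_d),
        armed=np.full((n, n), 1 if init.v < -60.0 else 0, dtype=np.uint8))
    return fld


def uniform_sheet(p: ModelParams, length: float, dx: float = 0.02,
                  dt: float = 0.01, diffusion: float = 0.001,
                  init: CellState | None = None) -> TissueField:
    """A homogeneous sheet (corner = center = p)."""
    spec = GradientSheetSpec(corner_params=p, center_params=p, length=length,
                             dx=dx, dt=dt, diffusion=diffusion)
    return build_gradient_sheet(spec, init=init)


def step_sheet(fld: TissueField, duration: float,
               stim_onsets=(), stim_amp: float = -30.0, stim_dur: float = 2.0,
               stim_mask: np.ndarray | None = None,
               probes=None, probe_every: int = 10,
               frames_every_ms: float = 0.0,
               stall_ms: float = 0.0, stop_on_far: bool = False,
               far: tuple[int, int] | None = None):
    """Advance the sheet ``duration`` ms (forward Euler, 5-point Laplacian,
    no-flux boundaries).  Returns (t_act, probe_rec, frames, frame_times,
    steps_done); state is updated in place."""
    spec = fld.spec
    ny, nx = fld.shape
    dt = spec.dt
    n_steps = int(round(duration / dt))
    if stim_mask is None:
        stim_mask = np.zeros((ny, nx), dtype=np.uint8)
    if probes is None:
        probes = [(ny // 2, nx // 2)]
    probes_y = np.array([p[0] for p in probes], dtype=np.int64)
    probes_x = np.array([p[1] for p in probes], dtype=np.int64)
    n_prec = (n_steps + probe_every - 1) // probe_every
    probe_rec = np.full((len(probes), n_prec), np.nan)
    if frames_every_ms > 0:
        frame_every = max(1, int(round(frames_every_ms / dt)))
        nf = (n_steps + frame_every - 1) // frame_every
        frames = np.empty((nf, ny, nx), dtype=np.float32)
    else:
        frame_every = 1
        frames = np.empty((0, ny, nx), dtype=np.float32)
    t_act = np.full((ny, nx), np.nan)
    if far is None:
        far = (ny - 1, nx - 1)
    steps = _kernels.sheet_run(
        fld.tabs, fld.pf, fld.svec, fld.v, fld.h, fld.w, fld.ca, fld.armed,
        dt, n_steps,
        spec.diffusion, spec.dx, stim_mask,
        np.asarray(stim_onsets, dtype=np.float64), stim_amp, stim_dur,
        probes_y, probes_x, probe_rec, probe_every,
        frames, frame_every, t_act, stall_ms, far[0], far[1], stop_on_far)
    if steps < 0:
        raise FloatingPointError("numerical blow-up in 2-D sheet simulation")
    frame_times = fld.t + np.arange(frames.shape[0]) * frame_every * dt
    probe_t = fld.t + np.arange(n_prec) * probe_every * dt
    t_act = t_act + fld.t
    fld.t += steps * dt
    n_done = min(n_prec, (steps + probe_every - 1) // probe_every)
    return dict(t_act=t_act, probe_t=probe_t[:n_done],
                probe_rec=probe_rec[:, :n_done], frames=frames,
                frame_times=frame_times, steps=steps,
                completed=steps == n_steps)


@dataclass
class SheetRun:
    """Everything recorded from one 2-D PES run."""

    spec: GradientSheetSpec
    proto: ProtocolSpec
    erps: list[float]
    stim_times: list[float]           # absolute onset of every stimulus
    apd_map: np.ndarray               # per-node APD of the final S1 beat
    act_maps: list[np.ndarray]        # activation-time maps of S1, S2..
    frames: np.ndarray                # float32 frames from S2 onward
    frame_times: np.ndarray
    probe_t: np.ndarray
    probe_rec: np.ndarray
    probes: list[tuple[int, int]]
    horizon: float                    # free-running time after last stimulus
    captured: list[bool] = field(default_factory=list)


def _corner_stim_mask(fld: TissueField) -> np.ndarray:
    n_stim = max(1, int(round(fld.spec.stim_size / fld.spec.dx)))
    m = np.zeros(fld.shape, dtype=np.uint8)
    m[:n_stim, :n_stim] = 1
    return m


def _sheet_capture(fld: TissueField, mask, proto, window) -> bool:
    snap = fld.state_copy()
    out = step_sheet(fld, window, stim_onsets=[0.0], stim_amp=proto.stim_amp,
                     stim_dur=proto.stim_dur, stim_mask=mask,
                     stop_on_far=True, stall_ms=60.0)
    captured = bool(np.isfinite(out["t_act"][-1, -1]))
    fld.state_restore(snap)
    return captured


def _corner_apd(samples_t, samples_v):
    """APD at the corner probe from chunk-boundary samples (may be NaN if
    the beat has not yet repolarised)."""
    t = np.asarray(samples_t)
    v = np.asarray(samples_v)
    up = np.nonzero((v[:-1] < DEPOL_THR) & (v[1:] >= DEPOL_THR))[0]
    if up.size == 0:
        return float("nan")
    fu = (DEPOL_THR - v[up[0]]) / (v[up[0] + 1] - v[up[0]])
    t_up = t[up[0]] + fu * (t[up[0] + 1] - t[up[0]])
    dn = np.nonzero((v[:-1] >= REPOL_THR) & (v[1:] < REPOL_THR))[0]
    dn = dn[t[dn] >= t_up]
    if dn.size == 0:
        return float("nan")
    fd = (v[dn[0]] - REPOL_THR) / (v[dn[0]] - v[dn[0] + 1])
    t_dn = t[dn[0]] + fd * (t[dn[0] + 1] - t[dn[0]])
    return float(t_dn - t_up)


def run_pes_2d(fld: TissueField, proto: ProtocolSpec | None = None,
               horizon: float = 2000.0, frames_every_ms: float = 4.0
               ) -> SheetRun:
    """Full 2-D PES: S1 drive from the bottom-left corner, S2–S4 delivered
    at their ERPs (5-ms increments by default), then a free-running
    horizon whose frames feed the reentry classifier.

    The sheet's nodes are pre-set to the paced diastolic state of the
    corner model, so the drive train converges within a few beats.  Each
    beat is "walked" in increments of the ERP scan step: a voltage frame
    and the corner-probe sample are taken at every chunk boundary, and once
    the walk passes 60 ms below the previous beat's corner APD each
    boundary hosts a capture trial (run on a copy of the state, so the
    substrate is untouched by failed trials).
    """
    if proto is None:
        proto = ProtocolSpec(erp_increment=5.0)
    spec = fld.spec
    ny, nx = fld.shape
    mask = _corner_stim_mask(fld)
    n_stim = max(1, int(round(spec.stim_size / spec.dx)))
    corner_probe = (n_stim + 1, n_stim + 1)
    probes = [corner_probe, (ny // 2, nx // 2), (ny - 3, nx - 3),
              (3, nx - 3), (ny - 3, 3)]
    inc = proto.erp_increment
    # pre-condition: paced diastolic state of the corner model
    _, pre, _ = sim.steady_state_pace(spec.corner_params, proto.bcl, 8,
                                      stim_amp=proto.stim_amp,
                                      stim_dur=proto.stim_dur)
    fld.v[:] = pre.v
    fld.h[:] = pre.h
    fld.w[:] = pre.w
    fld.ca[:] = pre.ca_d
    fld.armed[:] = 1 if pre.v < -60.0 else 0
    # S1 drive train (all but the final beat)
    prev_apd = float("nan")
    est_traversal = 2.0 * spec.length / 0.02
    for b in range(proto.n_s1 - 1):
        out = step_sheet(fld, proto.bcl, stim_onsets=[0.0],
                         stim_amp=proto.stim_amp, stim_dur=proto.stim_dur,
                         stim_mask=mask, probes=[corner_probe],
                         probe_every=max(1, int(round(1.0 / spec.dt))))
        if b == 0:
            if not np.isfinite(out["t_act"]).all():
                raise ProtocolFailure(
                    "S1 failed to propagate across the sheet")
            est_traversal = float(np.nanmax(out["t_act"]) -
                                  np.nanmin(out["t_act"]))
        prev_apd = _corner_apd(out["probe_t"], out["probe_rec"][0])
    if not np.isfinite(prev_apd):
        raise ProtocolFailure("corner APD of the drive train is undefined")
    cv_window = 4.0 * spec.length / 0.02 + 200.0  # generous traversal bound
    erps: list[float] = []
    captured: list[bool] = []
    stim_times: list[float] = []
    act_maps: list[np.ndarray] = []
    all_frames: list[np.ndarray] = []
    all_ftimes: list[float] = []
    probe_samples: list[np.ndarray] = []
    probe_times: list[float] = []
    apd_map = None

    def walk_beat(n_beat: int, scan: bool):
        """Deliver a stimulus now and walk forward in ``inc`` chunks,
        recording frames and probe samples; if ``scan``, run capture trials
        from (prev_apd − 60) onward and return the ERP walk result."""
        nonlocal apd_map
        t0 = fld.t
        stim_times.append(t0)
        frames_local: list[np.ndarray] = []
        times_local: list[float] = []
        t_act_total = np.full((ny, nx), np.nan)
        elapsed = 0.0
        start_scan = max(proto.stim_dur + 10.0, prev_apd - 60.0)
        erp = None
        while elapsed < proto.bcl + proto.scan_span:
            frames_local.append(fld.v.astype(np.float32))
            times_local.append(fld.t)
            probe_samples.append(np.array([fld.v[p] for p in probes]))
            probe_times.append(fld.t)
            # capture trials only once the preceding wavefront has cleared
            # the stimulus quadrant: otherwise the still-travelling wave
            # reaches the far corner during the trial window and would be
            # mistaken for a captured response.  (Distal wavelet activity
            # does not hold up the protocol: the clinical operator paces at
            # the local ERP regardless of what happens far away.)
            near = t_act_total[:max(4, ny // 3), :max(4, nx // 3)]
            if np.any(np.isfinite(near)):
                latest_act = float(np.nanmax(near)) - t0
            else:
                latest_act = 0.0
            # the current beat's own front must no longer be en route to
            # the far corner (it either arrived, or demonstrably died)
            far_done = bool(np.isfinite(t_act_total[ny - 1, nx - 1])) or \
                elapsed > est_traversal + 60.0
            if scan and erp is None and far_done and \
                    elapsed >= start_scan and \
                    elapsed >= latest_act + 25.0 and \
                    elapsed >= np.ceil(start_scan / inc) * inc:
                if _sheet_capture(fld, mask, proto, cv_window):
                    erp = elapsed
                    break
            onsets = [-elapsed] if elapsed < proto.stim_dur else []
            out = step_sheet(fld, inc, stim_onsets=onsets,
                             stim_amp=proto.stim_amp,
                             stim_dur=proto.stim_dur, stim_mask=mask)
            m = np.isnan(t_act_total)
            t_act_total[m] = out["t_act"][m]
            elapsed = fld.t - t0
            if not scan and elapsed >= proto.bcl:
                break
        act_maps.append(t_act_total)
        all_frames.extend(frames_local)
        all_ftimes.extend(times_local)
        return erp

    # final S1 beat (recorded, and hosts the S2 scan)
    erp = walk_beat(proto.n_s1 - 1, scan=True)
    if erp is None:
        raise ProtocolFailure("S2: no propagated capture within scan span")
    # measure the final S1 corner APD from recorded samples
    k0 = len(probe_times) - 1
    prev_apd_new = _corner_apd(probe_times, [s[0] for s in probe_samples])
    if np.isfinite(prev_apd_new):
        prev_apd = prev_apd_new
    for n in range(proto.n_premature):
        erps.append(float(erp))
        captured.append(True)
        last = n == proto.n_premature - 1
        if last:
            stim_times.append(fld.t)
            out = step_sheet(fld, horizon, stim_onsets=[0.0],
                             stim_amp=proto.stim_amp,
                             stim_dur=proto.stim_dur, stim_mask=mask,
                             probes=probes,
                             probe_every=max(1, int(round(2.0 / spec.dt))),
                             frames_every_ms=frames_every_ms)
            act_maps.append(out["t_act"])
            all_frames.extend(list(out["frames"]))
            all_ftimes.extend(list(out["frame_times"]))
            for kk in range(out["probe_t"].size):
                probe_samples.append(out["probe_rec"][:, kk])
                probe_times.append(out["probe_t"][kk])
            break
        seg_start = len(probe_times)
        erp = walk_beat(proto.n_s1 + n, scan=True)
        if erp is None:
            raise ProtocolFailure(
                f"S{n + 3}: no propagated capture within scan span")
        apd_n = _corner_apd([probe_times[k] for k in range(seg_start,
                                                           len(probe_times))],
                            [probe_samples[k][0] for k in
                             range(seg_start, len(probe_samples))])
        if np.isfinite(apd_n):
            prev_apd = apd_n
    frames = (np.stack(all_frames) if all_frames
              else np.empty((0, ny, nx), np.float32))
    # final-S1 APD map: exact activation times from the simulation, and the
    # first −75 mV down-crossing found anywhere in the later frames (the
    # premature beats interrupt the final S1 segment, but a node cannot be
    # re-excited before it has repolarized)
    apd_map = apd_map_from_frames(frames, np.array(all_ftimes),
                                  t_act=act_maps[0])
    return SheetRun(spec=spec, proto=proto, erps=erps, stim_times=stim_times,
                    apd_map=apd_map, act_maps=act_maps, frames=frames,
                    frame_times=np.array(all_ftimes),
                    probe_t=np.array(probe_times),
                    probe_rec=np.array(probe_samples).T,
                    probes=probes, horizon=horizon, captured=captured)


def apd_map_from_frames(frames: np.ndarray, frame_times: np.ndarray,
                        t_act: np.ndarray | None = None) -> np.ndarray:
    """Per-node APD from decimated frames.

    If ``t_act`` is given it supplies the exact upstroke times (from the
    simulation's activation bookkeeping); otherwise the upward −30 mV
    crossing is interpolated from the frames.  The repolarization time is
    the first −75 mV down-crossing after the upstroke."""
    nf, ny, nx = frames.shape
    v = frames.astype(np.float64)
    if t_act is not None:
        up_t = np.asarray(t_act, dtype=float).copy()
    else:
        up_t = np.full((ny, nx), np.nan)
    dn_t = np.full((ny, nx), np.nan)
    for k in range(nf - 1):
        a, b = v[k], v[k + 1]
        if t_act is None:
            m_up = np.isnan(up_t) & (a < DEPOL_THR) & (b >= DEPOL_THR)
            if m_up.any():
                frac = (DEPOL_THR - a[m_up]) / (b[m_up] - a[m_up])
                up_t[m_up] = frame_times[k] + frac * (frame_times[k + 1] -
                                                      frame_times[k])
        m_dn = (~np.isnan(up_t)) & np.isnan(dn_t) & (a >= REPOL_THR) & \
               (b < REPOL_THR) & (frame_times[k] >= up_t)
        if m_dn.any():
            frac = (a[m_dn] - REPOL_THR) / (a[m_dn] - b[m_dn])
            dn_t[m_dn] = frame_times[k] + frac * (frame_times[k + 1] -
                                                  frame_times[k])
    apd = dn_t - up_t
    # nodes whose repolarization was cut short by a re-exciting premature
    # wave (encroachment) have no valid APD for this beat
    apd[apd > 600.0] = np.nan
    return apd


def measure_apd_gradient(run: SheetRun) -> float:
    """APD gradient (ms/cm): difference between the sheet's longest APD and
    the APD at the lower-left corner, divided by the distance between the
    two sites."""
    apd = run.apd_map
    if np.all(np.isnan(apd)):
        raise ValueError("APD map is empty")
    jj, ii = np.unravel_index(np.nanargmax(apd), apd.shape)
    # lower-left corner: just outside the stimulus footprint
    n_stim = max(1, int(round(run.spec.stim_size / run.spec.dx)))
    j0 = i0 = n_stim + 1
    d = np.hypot((jj - j0) * run.spec.dx, (ii - i0) * run.spec.dx)
    if d == 0:
        return 0.0
    return float((apd[jj, ii] - apd[j0, i0]) / d)
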