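"""Classification of 2-D PES outcomes: extra beats, wave break, reentry,
and the VT/VF vocabulary.

Operational definitions (the package's own, documented choices):

* **Activation** — an upward −30 mV crossing, deduplicated by a 50-ms
  refractory gap.
* **Extra beats** — whole-tissue activations observed at the probe sites
  after the last stimulated beat's wave has passed.
* **Wave break** — a transient phase singularity: the activation front
  acquires an endpoint inside the tissue.  Phase is reconstructed per node
  from the voltage and a delayed copy, φ = atan2(V(t) − V*, V(t−τ) − V*),
  and singularities are found as ±2π winding numbers on 2×2 plaquettes.
* **Reentry** — a singularity that persists for at least one rotation
  period (estimated from the post-stimulus activation cycle length).
* **Sustained** — activity still present at the end of the free-running
  horizon (2 s in the full protocol).
* Labels: ``none``; ``eb(n)`` for n self-terminating extra beats;
  sustained single-rotor activity is ``vt`` (``vfvt`` when the cycle
  length is < 150 ms); multi-rotor activity (mean concurrent singularity
  count > 1.5) is ``vf`` when sustained and ``nsvf`` when it
  self-terminates after ≥ 3 extra beats.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import SheetRun

PHASE_VSTAR = -55.0
PHASE_LAG_MS = 8.0
ACT_THR = -30.0
REFRACT_GAP = 50.0
VFVT_CL = 150.0
VF_SINGS = 1.5


@dataclass
class ReentryOutcome:
    """Classified outcome of one 2-D PES run."""

    label: str
    wave_break: bool
    sustained_2s: bool
    n_rotations: int
    n_extra_beats: int = 0
    mean_singularities: float = 0.0
    cycle_length: float = float("nan")

    def __post_init__(self):
        if self.label == "none" and self.n_rotations != 0:
            raise ValueError("label 'none' implies zero rotations")


def detect_activations(t: np.ndarray, v: np.ndarray,
                       thr: float = ACT_THR,
                       gap: float = REFRACT_GAP) -> np.ndarray:
    """Activation times from a sampled voltage trace, deduplicated by a
    refractory gap."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    idx = np.nonzero((v[:-1] < thr) & (v[1:] >= thr))[0]
    times = []
    for i in idx:
        frac = (thr - v[i]) / (v[i + 1] - v[i])
        ti = t[i] + frac * (t[i + 1] - t[i])
        if not times or ti - times[-1] >= gap:
            times.append(ti)
    return np.array(times)


def phase_maps(frames: np.ndarray, frame_times: np.ndarray,
               vstar: float = PHASE_VSTAR,
               lag_ms: float = PHASE_LAG_MS) -> tuple[np.ndarray, np.ndarray]:
    """Per-node phase maps from voltage frames and a delayed copy."""
    if frames.shape[0] < 3:
        return np.empty((0,) + frames.shape[1:]), np.empty(0)
    dt_f = float(np.median(np.diff(frame_times)))
    lag = max(1, int(round(lag_ms / dt_f)))
    cur = frames[lag:].astype(np.float64)
    dly = frames[:-lag].astype(np.float64)
    ph = np.arctan2(cur - vstar, dly - vstar)
    return ph, frame_times[lag:]


def singularities_per_frame(ph: np.ndarray) -> np.ndarray:
    """Number of phase singularities (|winding| = 2π) in each phase map."""

    def wrap(a):
        return (a + np.pi) % (2.0 * np.pi) - np.pi

    counts = np.empty(ph.shape[0], dtype=int)
    for k in range(ph.shape[0]):
        p = ph[k]
        w = (wrap(p[1:, :-1] - p[:-1, :-1]) +
             wrap(p[1:, 1:] - p[1:, :-1]) +
             wrap(p[:-1, 1:] - p[1:, 1:]) +
             wrap(p[:-1, :-1] - p[:-1, 1:]))
        counts[k] = int(np.sum(np.abs(w) > 5.5))
    return counts


def measure_rotations(frames: np.ndarray, frame_times: np.ndarray,
                      at: tuple[int, int], vstar: float = PHASE_VSTAR,
                      lag_ms: float = PHASE_LAG_MS) -> float:
    """Net phase rotations at one node (unwrapped phase excursion / 2π)."""
    ph, _ = phase_maps(frames, frame_times, vstar, lag_ms)
    if ph.shape[0] == 0:
        return 0.0
    series = np.unwrap(ph[:, at[0], at[1]])
    return float(abs(series[-1] - series[0]) / (2.0 * np.pi))


def count_extra_beats(run: SheetRun) -> int:
    """Whole-tissue activations after the last stimulated beat (the
    stimulated wave itself is excluded)."""
    t_last = run.stim_times[-1]
    best = 0
    for q in range(run.probe_rec.shape[0]):
        acts = detect_activations(run.probe_t, run.probe_rec[q])
        extra = int(np.sum(acts > t_last)) - 1  # the last stimulated wave
        best = max(best, extra)
    return best


def _first_premature_time(run: SheetRun) -> float:
    if len(run.stim_times) >= 2:
        return run.stim_times[1]
    return run.stim_times[-1]


def detect_wavebreak(run: SheetRun) -> bool:
    """True if any transient phase singularity appears from the first
    premature beat onward."""
    ph, t = phase_maps(run.frames, run.frame_times)
    if ph.shape[0] == 0:
        return False
    counts = singularities_per_frame(ph[t >= _first_premature_time(run)])
    return bool(np.any(counts > 0))


def classify(run: SheetRun) -> ReentryOutcome:
    """Deterministic classification of a 2-D PES run."""
    t_last = run.stim_times[-1]
    n_extra = count_extra_beats(run)
    ph, pht = phase_maps(run.frames, run.frame_times)
    if ph.shape[0]:
        # wave break is assessed from the first premature beat onward;
        # the stimulated wavefronts themselves carry no singularities
        post = pht > _first_premature_time(run) + 20.0
        counts = singularities_per_frame(ph[post])
        times = pht[post]
    else:
        counts = np.empty(0, dtype=int)
        times = np.empty(0)
    wave_break = bool(np.any(counts > 0))
    # activity at the end of the horizon?
    end_t = run.probe_t[-1] if run.probe_t.size else t_last
    active_end = False
    for q in range(run.probe_rec.shape[0]):
        acts = detect_activations(run.probe_t, run.probe_rec[q])
        if acts.size and acts[-1] > end_t - 1.5 * max(200.0, REFRACT_GAP):
            active_end = True
    if run.frames.shape[0]:
        active_end = active_end or bool(
            np.mean(run.frames[-1] > ACT_THR) > 0.01)
    sustained = active_end
    # cycle length of post-stimulus activity
    cl = float("nan")
    cls = []
    for q in range(run.probe_rec.shape[0]):
        acts = detect_activations(run.probe_t, run.probe_rec[q])
        acts = acts[acts > t_last]
        if acts.size >= 2:
            cls.extend(np.diff(acts))
    if cls:
        cl = float(np.median(cls))
    # reentry requires a completed rotation, i.e. re-excitation of the
    # tissue: a singularity must persist AND emit at least one extra beat
    # (wave break alone is a fragmented front that dies without rotating)
    persistent = False
    if counts.size and np.any(counts > 0):
        dt_f = float(np.median(np.diff(times))) if times.size > 1 else 4.0
        longest = 0
        cur = 0
        for c in counts:
            cur = cur + 1 if c > 0 else 0
            longest = max(longest, cur)
        persistent = longest * dt_f >= 60.0
    reentry = persistent and n_extra >= 1
    mean_sing = float(np.mean(counts[counts > 0])) if np.any(counts > 0) else 0.0
    n_rot = n_extra if (reentry or n_extra > 0) else 0
    if n_extra <= 0 and not reentry:
        return ReentryOutcome("none", wave_break, False, 0,
                              n_extra_beats=max(0, n_extra),
                              mean_singularities=mean_sing, cycle_length=cl)
    if not sustained:
        if mean_sing > VF_SINGS and n_extra >= 3:
            label = "nsvf"
        else:
            label = f"eb{max(n_extra, 1)}"
        return ReentryOutcome(label, wave_break, False, n_rot,
                              n_extra_beats=n_extra,
                              mean_singularities=mean_sing, cycle_length=cl)
    if mean_sing > VF_SINGS:
        label = "vf"
    elif np.isfinite(cl) and cl < VFVT_CL:
        label = "vfvt"
    else:
        label = "vt"
    return ReentryOutcome(label, wave_break, True, n_rot,
                          n_extra_beats=n_extra,
                          mean_singularities=mean_sing, cycle_length=cl)
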