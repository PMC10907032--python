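"""Compiled forward-Euler integrators for cell, cable, and 2-D sheet.

These kernels evaluate the ionic model through shared voltage lookup tables
(built by :func:`cardiopes.ionic.build_tables`) with linear interpolation on
a 0.05 mV grid; direct transcendental evaluation is reserved for the
reference right-hand side used by the adaptive oracle integrator in tests.

Parameter vector layout (``pvec``), one value per entry (cell/cable) or one
field per entry (sheet):

    0 g_na   1 g_cal   2 g_kr   3 g_ks   4 g_k1   5 g_to
    6 tauh_scale   7 eh_shift

Scalar parameters shared by all nodes (``svec``):

    0 tau_w   1 ca_gain   2 ca_decay   3 ca_sat   4 ca_alpha

State is (v, h, w, ca_d).  Gates are clipped to [0, 1] after each step.
All kernels return the number of steps actually executed (early stopping)
or -1 on numerical blow-up.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .ionic import DV_TAB, V_TAB_MIN

_INV_DV = 1.0 / DV_TAB


@njit(inline="always", cache=True)
def _interp(tab, v):
    x = (v - V_TAB_MIN) * _INV_DV
    if x < 0.0:
        x = 0.0
    n = tab.shape[0]
    if x > n - 1.001:
        x = n - 1.001
    i = int(x)
    f = x - i
    return tab[i] + f * (tab[i + 1] - tab[i])


@njit(cache=True)
def cell_run(tabs, pvec, svec, state, dt, n_steps,
             stim_onsets, stim_amp, stim_dur,
             rec_every, v_rec, ina_rec, ical_rec, out,
             snap_every, snaps):
    """Integrate a single cell for ``n_steps`` of size ``dt``.

    ``stim_onsets`` are times (ms, relative to kernel start) at which a
    rectangular stimulus of ``stim_amp`` µA/cm² and ``stim_dur`` ms begins.
    ``v_rec``/``ina_rec``/``ical_rec`` are filled every ``rec_every`` steps.
    ``out`` receives [max ionic dV/dt, min I_Na, min I_Ca,L] over the run
    (the stimulus term is excluded from the dV/dt bookkeeping so upstroke
    velocity is free of stimulus artifact).  If ``snap_every`` > 0 the full
    state (v, h, w, ca) is copied into ``snaps`` every ``snap_every`` steps
    (row k holds the state at step k*snap_every, i.e. before that step),
    which the ERP searches use as restart points.
    """
    gna, gcal, gkr, gks, gk1, gto = pvec[0], pvec[1], pvec[2], pvec[3], pvec[4], pvec[5]
    tauhs, ehs = pvec[6], pvec[7]
    tau_w, ca_gain, ca_decay, ca_sat, ca_alpha = svec[0], svec[1], svec[2], svec[3], svec[4]
    v, h, w, ca = state[0], state[1], state[2], state[3]
    max_dvdt = -1.0e30
    min_ina = 1.0e30
    min_ical = 1.0e30
    n_stim = stim_onsets.shape[0]
    si = 0
    nrec = 0
    nsnap = 0
    for k in range(n_steps):
        t = k * dt
        istim = 0.0
        while si < n_stim and t >= stim_onsets[si] + stim_dur:
            si += 1
        if si < n_stim and stim_onsets[si] <= t:
            istim = stim_amp
        if snap_every > 0 and k % snap_every == 0 and nsnap < snaps.shape[0]:
            snaps[nsnap, 0] = v
            snaps[nsnap, 1] = h
            snaps[nsnap, 2] = w
            snaps[nsnap, 3] = ca
            nsnap += 1
        ina = gna * _interp(tabs[0], v) * h
        ical = gcal * _interp(tabs[1], v) * w
        ik = (gkr * _interp(tabs[2], v) + gks * _interp(tabs[3], v) +
              gk1 * _interp(tabs[4], v) + gto * _interp(tabs[5], v))
        dvdt_ion = -(ina + ical + ik)
        if dvdt_ion > max_dvdt:
            max_dvdt = dvdt_ion
        if ina < min_ina:
            min_ina = ina
        if ical < min_ical:
            min_ical = ical
        if k % rec_every == 0:
            v_rec[nrec] = v
            ina_rec[nrec] = ina
            ical_rec[nrec] = ical
            nrec += 1
        hinf = _interp(tabs[6], v - ehs)
        tau_h = tauhs * (1.0 + ca_alpha * ca) * _interp(tabs[7], v)
        winf = _interp(tabs[8], v)
        v = v + dt * (dvdt_ion - istim)
        h = h + dt * (hinf - h) / tau_h
        w = w + dt * (winf - w) / tau_w
        ca = ca + dt * (ca_gain * abs(ical) - ca_decay * ca / (1.0 + ca / ca_sat))
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        if ca < 0.0:
            ca = 0.0
        if v > 500.0 or v < -500.0 or v != v:
            return -1
    state[0], state[1], state[2], state[3] = v, h, w, ca
    out[0], out[1], out[2] = max_dvdt, min_ina, min_ical
    return n_steps


@njit(cache=True)
def cable_run(tabs, pvec, svec, v, h, w, ca, armed, dt, n_steps, diff, dx,
              n_stim_nodes, stim_onsets, stim_amp, stim_dur,
              rec_node, rec_every, v_rec, ina_rec, t_act,
              far_mode, stall_ms, out):
    """Integrate a uniform 1-D cable (no-flux ends, 3-point Laplacian).

    The stimulus is injected into the first ``n_stim_nodes`` nodes.
    ``t_act`` (NaN-initialised, length n) records the first upward −30 mV
    crossing time of each node, linearly interpolated.  ``far_mode``
    controls early stopping: 1 = stop as soon as the last node activates
    (capture trials); 2 = stop once the last node has activated *and* the
    recording node has repolarised below −75 mV (measurement runs).  If
    ``stall_ms`` > 0 the kernel returns early when no new node has
    activated for that long while the far end is still silent.
    ``out`` receives [min I_Na at rec_node, max ionic dV/dt at rec_node].
    """
    n = v.shape[0]
    tau_w, ca_gain, ca_decay, ca_sat, ca_alpha = svec[0], svec[1], svec[2], svec[3], svec[4]
    gna, gcal, gkr, gks, gk1, gto = pvec[0], pvec[1], pvec[2], pvec[3], pvec[4], pvec[5]
    tauhs, ehs = pvec[6], pvec[7]
    r = diff / (dx * dx)
    n_stim = stim_onsets.shape[0]
    si = 0
    nrec = 0
    min_ina = 1.0e30
    max_dvdt = -1.0e30
    last_new_act = 0.0
    vnew = np.empty(n)
    # ``armed``: a node must repolarize below -60 mV before a -30 mV
    # upstroke counts as a new activation (passive wobbles near threshold
    # are not beats); the flag persists across kernel calls
    steps_done = n_steps
    for k in range(n_steps):
        t = k * dt
        istim = 0.0
        while si < n_stim and t >= stim_onsets[si] + stim_dur:
            si += 1
        if si < n_stim and stim_onsets[si] <= t:
            istim = stim_amp
        for i in range(n):
            vi = v[i]
            ina = gna * _interp(tabs[0], vi) * h[i]
            ical = gcal * _interp(tabs[1], vi) * w[i]
            ik = (gkr * _interp(tabs[2], vi) + gks * _interp(tabs[3], vi) +
                  gk1 * _interp(tabs[4], vi) + gto * _interp(tabs[5], vi))
            dv_ion = -(ina + ical + ik)
            if i == rec_node:
                if ina < min_ina:
                    min_ina = ina
                if dv_ion > max_dvdt:
                    max_dvdt = dv_ion
                if k % rec_every == 0:
                    v_rec[nrec] = vi
                    ina_rec[nrec] = ina
                    nrec += 1
            if i == 0:
                lap = 2.0 * (v[1] - vi)
            elif i == n - 1:
                lap = 2.0 * (v[n - 2] - vi)
            else:
                lap = v[i - 1] - 2.0 * vi + v[i + 1]
            dv = dv_ion + r * lap
            if i < n_stim_nodes:
                dv -= istim
            vn = vi + dt * dv
            hinf = _interp(tabs[6], vi - ehs)
            tau_h = tauhs * (1.0 + ca_alpha * ca[i]) * _interp(tabs[7], vi)
            winf = _interp(tabs[8], vi)
            hn = h[i] + dt * (hinf - h[i]) / tau_h
            wn = w[i] + dt * (winf - w[i]) / tau_w
            cn = ca[i] + dt * (ca_gain * abs(ical) -
                               ca_decay * ca[i] / (1.0 + ca[i] / ca_sat))
            if hn < 0.0:
                hn = 0.0
            elif hn > 1.0:
                hn = 1.0
            if wn < 0.0:
                wn = 0.0
            elif wn > 1.0:
                wn = 1.0
            if cn < 0.0:
                cn = 0.0
            if vn != vn or vn > 500.0 or vn < -500.0:
                return -1
            if vn < -60.0:
                armed[i] = 1
            elif armed[i] == 1 and t_act[i] != t_act[i] and \
                    vn >= -30.0 and vi < -30.0:
                t_act[i] = t + dt * (-30.0 - vi) / (vn - vi)
                armed[i] = 0
                last_new_act = t
            vnew[i] = vn
            h[i], w[i], ca[i] = hn, wn, cn
        for i in range(n):
            v[i] = vnew[i]
        far_act = t_act[n - 1] == t_act[n - 1]
        if far_mode == 1 and far_act:
            steps_done = k + 1
            break
        # a small margin below the repolarization threshold ensures the
        # decimated recording still brackets the -75 mV crossing
        if far_mode == 2 and far_act and v[rec_node] < -78.0:
            steps_done = k + 1
            break
        if stall_ms > 0.0 and not far_act:
            if t - last_new_act > stall_ms:
                steps_done = k + 1
                break
    out[0], out[1] = min_ina, max_dvdt
    return steps_done


@njit(cache=True)
def sheet_run(tabs, pf, svec, v, h, w, ca, armed, dt, n_steps, diff, dx,
              stim_mask, stim_onsets, stim_amp, stim_dur,
              probes_y, probes_x, probe_rec, probe_every,
              frames, frame_every, t_act, stall_ms, far_y, far_x, stop_on_far):
    """Integrate an isotropic monodomain 2-D sheet (no-flux boundaries,
    5-point Laplacian).

    ``pf`` holds the eight per-node parameter fields (8, ny, nx) so tissue
    gradients are supported.  ``stim_mask`` (ny, nx, uint8) marks stimulated
    nodes.  Probe voltages are recorded every ``probe_every`` steps; frames
    (float32, decimated) every ``frame_every`` steps (``frames`` may have
    zero length to disable).  ``t_act`` records first upward −30 mV
    crossings since kernel start.  Early stopping mirrors the cable kernel,
    with the "far" site given by (far_y, far_x).
    """
    ny, nx = v.shape
    tau_w, ca_gain, ca_decay, ca_sat, ca_alpha = svec[0], svec[1], svec[2], svec[3], svec[4]
    r = diff / (dx * dx)
    n_stim = stim_onsets.shape[0]
    si = 0
    n_probe = probes_y.shape[0]
    nprec = 0
    nfr = 0
    max_frames = frames.shape[0]
    last_new_act = 0.0
    vnew = np.empty((ny, nx))
    # same persistent arming rule as the cable kernel
    steps_done = n_steps
    for k in range(n_steps):
        t = k * dt
        istim = 0.0
        while si < n_stim and t >= stim_onsets[si] + stim_dur:
            si += 1
        if si < n_stim and stim_onsets[si] <= t:
            istim = stim_amp
        if k % probe_every == 0 and nprec < probe_rec.shape[1]:
            for q in range(n_probe):
                probe_rec[q, nprec] = v[probes_y[q], probes_x[q]]
            nprec += 1
        if max_frames > 0 and k % frame_every == 0 and nfr < max_frames:
            for j in range(ny):
                for i in range(nx):
                    frames[nfr, j, i] = v[j, i]
            nfr += 1
        any_new = False
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for i in range(nx):
                im = i - 1 if i > 0 else 1
                ip = i + 1 if i < nx - 1 else nx - 2
                vi = v[j, i]
                ina = pf[0, j, i] * _interp(tabs[0], vi) * h[j, i]
                ical = pf[1, j, i] * _interp(tabs[1], vi) * w[j, i]
                ik = (pf[2, j, i] * _interp(tabs[2], vi) +
                      pf[3, j, i] * _interp(tabs[3], vi) +
                      pf[4, j, i] * _interp(tabs[4], vi) +
                      pf[5, j, i] * _interp(tabs[5], vi))
                lap = (v[j, im] + v[j, ip] + v[jm, i] + v[jp, i] - 4.0 * vi)
                dv = -(ina + ical + ik) + r * lap
                if istim != 0.0 and stim_mask[j, i] == 1:
                    dv -= istim
                vn = vi + dt * dv
                hinf = _interp(tabs[6], vi - pf[7, j, i])
                tau_h = pf[6, j, i] * (1.0 + ca_alpha * ca[j, i]) * _interp(tabs[7], vi)
                winf = _interp(tabs[8], vi)
                hn = h[j, i] + dt * (hinf - h[j, i]) / tau_h
                wn = w[j, i] + dt * (winf - w[j, i]) / tau_w
                cn = ca[j, i] + dt * (ca_gain * abs(ical) -
                                      ca_decay * ca[j, i] / (1.0 + ca[j, i] / ca_sat))
                if hn < 0.0:
                    hn = 0.0
                elif hn > 1.0:
                    hn = 1.0
                if wn < 0.0:
                    wn = 0.0
                elif wn > 1.0:
                    wn = 1.0
                if cn < 0.0:
                    cn = 0.0
                if vn != vn or vn > 500.0 or vn < -500.0:
                    return -1
                if vn < -60.0:
                    armed[j, i] = 1
                elif armed[j, i] == 1 and t_act[j, i] != t_act[j, i] and \
                        vn >= -30.0 and vi < -30.0:
                    t_act[j, i] = t + dt * (-30.0 - vi) / (vn - vi)
                    armed[j, i] = 0
                    any_new = True
                vnew[j, i] = vn
                h[j, i], w[j, i], ca[j, i] = hn, wn, cn
        for j in range(ny):
            for i in range(nx):
                v[j, i] = vnew[j, i]
        if any_new:
            last_new_act = t
        far_done = t_act[far_y, far_x] == t_act[far_y, far_x]
        if stop_on_far and far_done:
            steps_done = k + 1
            break
        if stall_ms > 0.0 and not far_done and t - last_new_act > stall_ms:
            steps_done = k + 1
            break
    return steps_done
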