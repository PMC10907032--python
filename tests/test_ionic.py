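"""Unit and property tests of the single-cell ionic model."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from cardiopes import ionic, pes, sim
from cardiopes.params import CellState


def test_tau_h_voltage_dependence(control):
    """TauH is sub-millisecond at plateau potentials, peaks near 7 ms in
    the phase-3/diastolic range, and is strictly positive everywhere."""
    v = np.arange(-120.0, 60.0, 0.5)
    tau = ionic.tau_h(v, control)
    assert np.all(tau > 0)
    assert np.all(tau[v >= -30.0] < 1.0)
    peak_band = (v >= -90.0) & (v <= -60.0)
    assert tau.max() == tau[peak_band].max()
    assert tau.max() == pytest.approx(7.0, abs=0.5)


def test_tau_h_scaling_identity(control):
    v = np.linspace(-100, 40, 57)
    doubled = control.replace(tauh_scale=2.0)
    assert np.allclose(ionic.tau_h(v, doubled), 2.0 * ionic.tau_h(v, control))


def test_tau_h_scaling_of_recovery_time_course(control):
    """Multiplying tauh_scale by k stretches the voltage-clamped recovery
    of h by exactly k (cross-checked against the closed-form exponential)."""
    v_hold = -85.0
    h0 = 0.05
    hinf = float(ionic.h_inf(v_hold, control))

    def recover(scale):
        p = control.replace(tauh_scale=scale)
        tau = float(ionic.tau_h(v_hold, p))
        # time for h to reach halfway to steady state
        sol = solve_ivp(lambda t, y: (hinf - y) / tau, (0, 50 * scale),
                        [h0], rtol=1e-10, atol=1e-12, dense_output=True)
        target = h0 + 0.5 * (hinf - h0)
        ts = np.linspace(0, 50 * scale, 20001)
        ys = sol.sol(ts)[0]
        return ts[np.argmin(np.abs(ys - target))], tau

    t1, tau1 = recover(1.0)
    t3, tau3 = recover(3.0)
    assert t3 / t1 == pytest.approx(3.0, rel=0.01)
    # halfway time of an exponential is tau * ln 2
    assert t1 == pytest.approx(tau1 * np.log(2.0), rel=0.02)


def test_initial_state(control):
    s = ionic.initial_state(control)
    assert s.v == -88.0
    assert 0.0 <= s.h <= 1.0 and 0.0 <= s.w <= 1.0
    assert s.ca_d == 0.0
    assert s.h == pytest.approx(float(ionic.h_inf(-88.0, control)))
    assert s.w == pytest.approx(float(ionic.w_inf(-88.0)))


def test_current_identities(control):
    s = ionic.initial_state(control)
    s.v = control.e_na
    cs = ionic.ionic_currents(s, control)
    assert cs.i_na == 0.0
    s2 = CellState(v=-20.0, h=0.0, w=0.5)
    assert ionic.ionic_currents(s2, control).i_na == 0.0
    cs3 = ionic.ionic_currents(CellState(v=-20.0, h=0.3, w=0.5), control)
    total = (cs3.i_na + cs3.i_cal + cs3.i_kr + cs3.i_ks + cs3.i_k1 +
             cs3.i_to)
    assert cs3.i_total == pytest.approx(total, rel=1e-12)


def test_resting_potential_root_matches_initialisation(control):
    """Brute-force bisection of the steady-state current-voltage relation
    finds the resting potential the model is initialised at."""

    def i_ss(v):
        s = CellState(v=v, h=float(ionic.h_inf(v, control)),
                      w=float(ionic.w_inf(v)))
        return ionic.ionic_currents(s, control).i_total

    v_rest = bisect(i_ss, -110.0, -60.0, xtol=1e-9)
    assert v_rest == pytest.approx(-88.0, abs=0.05)


def test_resting_stability(control):
    """Unstimulated, the equilibrated resting state drifts < 0.5 mV over
    10 seconds."""
    s = ionic.initial_state(control)
    tr, s10 = sim.simulate_cell(control, s, 10_000.0, rec_ms=10.0)
    assert abs(s10.v - s.v) < 0.5
    assert np.ptp(tr.v) < 0.5


def test_step_cell_rest_is_fixed_point(control):
    s = ionic.initial_state(control)
    s2 = ionic.step_cell(s, control, i_stim=0.0, dt=0.001)
    assert abs(s2.v - s.v) < 1e-9
    assert abs(s2.h - s.h) < 1e-9


def test_euler_dt_convergence(control):
    """APD at dt = 0.001 and dt = 0.0005 agree within 0.5 ms."""
    apds = []
    for dt in (0.001, 0.0005):
        tr, _, _ = sim.steady_state_pace(control, 400.0, 4, dt=dt)
        apds.append(pes.measure_apd(tr))
    assert abs(apds[0] - apds[1]) < 0.5


def test_euler_matches_adaptive_stiff_oracle(control):
    """A paced beat integrated by the table-based Euler kernel agrees with
    an adaptive stiff integration of the identical right-hand side to
    within 1 ms of APD."""
    _, _, info = sim.steady_state_pace(control, 400.0, 7)
    st = info["final_state"]
    tr, _ = sim.simulate_cell(control, st, 400.0, stim_onsets=[0.0])
    apd_euler = pes.measure_apd(tr)
    y0 = st.as_array()
    s1 = solve_ivp(lambda t, y: ionic.rhs(t, y, control, -30.0), (0, 2), y0,
                   method="LSODA", rtol=1e-8, atol=1e-9, dense_output=True)
    s2 = solve_ivp(lambda t, y: ionic.rhs(t, y, control, 0.0), (2, 400),
                   s1.y[:, -1], method="LSODA", rtol=1e-8, atol=1e-9,
                   max_step=5.0, dense_output=True)
    t = np.concatenate([np.arange(0, 2, 0.01), np.arange(2, 400, 0.05)])
    v = np.concatenate([s1.sol(np.arange(0, 2, 0.01))[0],
                        s2.sol(np.arange(2, 400, 0.05))[0]])
    apd_oracle = pes.measure_apd(sim.Trace(t=t, v=v))
    assert abs(apd_euler - apd_oracle) < 1.0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(amp=st.floats(-80.0, -1.0), bcl=st.floats(80.0, 500.0),
       n=st.integers(1, 3))
def test_gates_stay_bounded(amp, bcl, n):
    """For arbitrary stimulus trains the gating variables remain in [0, 1]
    and the trajectory stays finite."""
    from cardiopes import variants
    p = variants.make_control()
    s = ionic.initial_state(p)
    for _ in range(n):
        tr, s = sim.simulate_cell(p, s, bcl, stim_onsets=[0.0],
                                  stim_amp=amp, rec_ms=1.0)
        assert np.all(np.isfinite(tr.v))
        assert 0.0 <= s.h <= 1.0
        assert 0.0 <= s.w <= 1.0
        assert s.ca_d >= 0.0


def test_premature_sodium_current_monotone_in_coupling(control):
    """Peak I_Na of a premature beat grows in magnitude with the coupling
    interval (refractory monotonicity).  Coupling intervals are referenced
    to the last drive stimulus."""
    _, _, info = sim.steady_state_pace(control, 400.0, 7)
    st = info["final_state"]
    peaks = []
    for ci in (236.0, 245.0, 260.0, 320.0, 395.0):
        tr, _ = sim.simulate_cell(control, st, ci + 60.0,
                                  stim_onsets=[0.0, ci])
        # peak of the premature response only (after its stimulus onset)
        sel = tr.t - tr.t[0] >= ci
        peaks.append(float(np.min(tr.i_na[sel])))
    # non-decreasing magnitude within a 0.5 µA/cm² granularity (the last
    # two intervals are both essentially fully recovered)
    assert all(b <= a + 0.5 for a, b in zip(peaks, peaks[1:]))
    assert peaks[-1] < -100.0


def test_no_capture_reported(control):
    with pytest.raises(RuntimeError, match="suprathreshold"):
        sim.steady_state_pace(control, 400.0, 2, stim_amp=-0.01)
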