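"""PES engine tests: APD measurement, capture criteria, ERP-search
correctness, cable conduction."""
import numpy as np
import pytest

from cardiopes import pes, sim


def test_measure_apd_square_pulse():
    """A synthetic square pulse from −88 to 0 mV lasting 100 ms has an APD
    of 100 ms (both thresholds crossed at the pulse edges)."""
    t = np.arange(0.0, 200.0, 0.05)
    v = np.where((t >= 20.0) & (t < 120.0), 0.0, -88.0)
    apd = pes.measure_apd(sim.Trace(t=t, v=v))
    assert apd == pytest.approx(100.0, abs=0.1)


def test_measure_apd_requires_crossings():
    t = np.arange(0.0, 50.0, 0.05)
    with pytest.raises(ValueError):
        pes.measure_apd(sim.Trace(t=t, v=np.full_like(t, -88.0)))


def test_capture_boundary_is_strict():
    tr = sim.Trace(t=np.arange(3.0), v=np.zeros(3),
                   meta={"peak_i_na": -100.0})
    assert not pes.capture_test_cell(tr)
    tr.meta["peak_i_na"] = -100.01
    assert pes.capture_test_cell(tr)
    tr.meta["peak_i_na"] = -62.0
    assert not pes.capture_test_cell(tr)
    tr.meta["peak_i_na"] = -322.0
    assert pes.capture_test_cell(tr)


def test_protocol_spec_validation():
    with pytest.raises(ValueError):
        pes.ProtocolSpec(erp_increment=0.0)
    with pytest.raises(ValueError):
        pes.ProtocolSpec(stim_amp=30.0)


def test_erp_search_matches_exhaustive_scan(control):
    """The production ERP search agrees with a brute-force 1-ms scan over
    the whole coupling-interval range, and ERP−1 ms fails to capture."""
    proto = pes.ProtocolSpec()
    res = pes.run_pes_cell(control, proto)
    erp = res.beat("S2").erp
    _, _, info = sim.steady_state_pace(control, proto.bcl, proto.n_s1 - 1)
    pre = info["final_state"]
    trace, snaps = pes._chunked_cell_beat(control, pre, 640.0, proto,
                                          stim=True)
    apd1 = pes.measure_apd(trace)
    assert apd1 == pytest.approx(res.beat("S1").apd, abs=0.1)
    # exhaustive oracle scan
    found = None
    ci = 10.0
    while ci < 600.0:
        if pes._cell_capture(control, snaps[int(round(ci))], proto):
            found = ci
            break
        ci += 1.0
    assert found == pytest.approx(erp)
    assert not pes._cell_capture(control, snaps[int(round(erp - 1))], proto)
    assert pes._cell_capture(control, snaps[int(round(erp))], proto)


def test_control_apd_shortens_through_premature_beats(control):
    """Premature-beat APD shortens sharply from the drive beat and does
    not regrow through S3/S4 (restitution; the later beats sit on the
    short-DI floor of the restitution curve)."""
    res = pes.run_pes_cell(control)
    apds = [b.apd for b in res.beats]
    assert apds[1] < apds[0] - 20.0
    assert all(b <= a + 0.5 for a, b in zip(apds[1:], apds[2:]))
    assert res.beat("S1").d_top == 0.0


def test_no_stimulus_no_capture(control):
    proto = pes.ProtocolSpec(stim_amp=-0.01)
    with pytest.raises((pes.ProtocolFailure, RuntimeError)):
        pes.run_pes_cell(control, proto)


def test_cable_cv_diffusion_scaling(control):
    """CV scales as sqrt(D): doubling the diffusion coefficient increases
    CV by sqrt(2) within 3 %."""
    # fine dx so the depolarization front stays resolved at both D values
    spec1 = pes.CableSpec(length=2.5, dx=0.005, diffusion=0.001)
    spec2 = pes.CableSpec(length=2.5, dx=0.005, diffusion=0.002)
    cv1 = pes.measure_cv(control, spec1)
    cv2 = pes.measure_cv(control, spec2)
    assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.03)


def test_cable_short_fixture_cv_positive(control):
    from cardiopes import scenarios
    cfg, manifest = scenarios.make_fixture("cable_short")
    cv = pes.measure_cv(control, pes.CableSpec(length=cfg["length"],
                                               dx=cfg["dx"],
                                               diffusion=cfg["diffusion"]))
    assert np.isfinite(cv) and cv > 0


def test_pes_result_tidy_export(control):
    res = pes.run_pes_cell(control)
    df = res.to_frame()
    assert set(df.columns) == {"variant", "context", "beat", "metric",
                               "value"}
    assert set(df.beat.unique()) == {"S1", "S2", "S3", "S4"}
    prr = df[(df.metric == "prr") & (df.beat == "S2")].value.iloc[0]
    assert prr == pytest.approx(res.beat("S2").prr)
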