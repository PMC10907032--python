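"""Classifier ground-truth tests on prescribed synthetic fields."""
import numpy as np
import pytest

from cardiopes import classify, scenarios


@pytest.fixture(scope="module")
def spiral():
    cfg, manifest = scenarios.make_fixture("spiral_synthetic")
    frames, times = scenarios.synthetic_spiral(cfg)
    return cfg, manifest, frames, times


def test_synthetic_spiral_singularity_count_exact(spiral):
    cfg, manifest, frames, times = spiral
    ph, t = classify.phase_maps(frames, times, vstar=cfg["vstar"])
    counts = classify.singularities_per_frame(ph)
    assert counts.size > 100
    assert np.all(counts == manifest["n_singularities"])


def test_synthetic_spiral_rotation_count_exact(spiral):
    cfg, manifest, frames, times = spiral
    ny, nx = cfg["ny"], cfg["nx"]
    rot = classify.measure_rotations(frames, times,
                                     at=(ny // 2 + 6, nx // 2 + 6),
                                     vstar=cfg["vstar"])
    # the phase embedding loses one lag interval at the start
    expected = (times[-1] - times[0] - classify.PHASE_LAG_MS) / \
        cfg["period_ms"]
    assert rot == pytest.approx(expected, abs=0.15)


def test_quiescent_field_has_no_singularities():
    frames = np.full((50, 40, 40), -88.0, dtype=np.float32)
    times = np.arange(50) * 4.0
    ph, _ = classify.phase_maps(frames, times)
    counts = classify.singularities_per_frame(ph)
    assert np.all(counts == 0)


def test_detect_activations_counts_and_dedup():
    t = np.arange(0.0, 2000.0, 1.0)
    v = np.full_like(t, -88.0)
    for onset in (100, 500, 900, 1300):  # four square APs
        v[(t >= onset) & (t < onset + 200)] = 0.0
    acts = classify.detect_activations(t, v)
    assert acts.size == 4
    # a jittery double-crossing within the refractory gap is deduplicated
    v2 = v.copy()
    v2[(t >= 102) & (t < 104)] = -40.0
    acts2 = classify.detect_activations(t, v2)
    assert acts2.size == 4


def test_activation_bookkeeping_on_quiescent_trace():
    t = np.arange(0.0, 100.0, 1.0)
    assert classify.detect_activations(t, np.full_like(t, -88.0)).size == 0


def test_reentry_outcome_invariant():
    with pytest.raises(ValueError):
        classify.ReentryOutcome(label="none", wave_break=False,
                                sustained_2s=False, n_rotations=2)
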