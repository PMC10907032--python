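"""Variant-factory tests: factor bookkeeping, axes enumeration,
composition algebra."""
import numpy as np
import pytest

from cardiopes import variants
from cardiopes.variants import (am_axes, apply_factors, apply_hf, apply_ds,
                                apply_tauh_prime, compose_hf_drug, factors_of)


def test_hf_conductance_factors(control):
    hf = apply_hf(control, g_na_factor=0.61)
    assert hf.g_ks == pytest.approx(control.g_ks * 0.42)
    assert hf.g_k1 == pytest.approx(control.g_k1 * 0.59)
    assert hf.g_to == pytest.approx(control.g_to * 0.56)
    assert hf.g_cal == pytest.approx(control.g_cal * 0.75)
    assert hf.g_na == pytest.approx(control.g_na * 0.61)
    assert hf.g_kr == control.g_kr  # I_Kr untouched by HF remodeling


def test_hf_zero_conductances_stay_zero():
    p = variants.make_control().replace(g_ks=0.0, g_k1=0.0, g_to=0.0,
                                        g_cal=0.0)
    hf = apply_hf(p, g_na_factor=0.61)
    assert hf.g_ks == hf.g_k1 == hf.g_to == hf.g_cal == 0.0


def test_hf_not_idempotent(control):
    once = apply_hf(control, g_na_factor=0.61)
    twice = apply_hf(once, g_na_factor=0.61)
    assert twice.g_ks == pytest.approx(control.g_ks * 0.42 ** 2)
    assert twice.g_ks != pytest.approx(once.g_ks)


def test_ds_factors(control):
    ds = apply_ds(control, kr_factor=0.77)
    assert ds.g_kr == pytest.approx(control.g_kr * 0.77)
    assert ds.tauh_scale == pytest.approx(2.0)
    assert ds.g_na == control.g_na


def test_am_axes_enumerate_eight_distinct():
    axes = [am_axes(i) for i in range(1, 9)]
    assert len(set(axes)) == 8
    assert am_axes(1) == (False, False, False)
    assert am_axes(8) == (True, True, True)
    with pytest.raises(ValueError):
        am_axes(9)


def test_tauh_prime_overwrites_only_tauh(control):
    fake_am = control.replace(tauh_scale=15.0, g_na=4.0, eh_shift=-10.8,
                              label="am4")
    prime = apply_tauh_prime(fake_am)
    assert prime.tauh_scale == 2.0
    assert prime.g_na == fake_am.g_na
    assert prime.eh_shift == fake_am.eh_shift
    assert prime.label == "am4p"


def test_composition_product_rule_and_order_independence(control):
    hf = apply_hf(control, g_na_factor=0.61)
    drug = apply_ds(control, kr_factor=0.77).replace(eh_shift=-10.8)
    hf_d = factors_of(hf, control)
    drug_d = factors_of(drug, control)
    combo = compose_hf_drug(hf_d, drug_d, base=control)
    assert combo.g_k1 == pytest.approx(control.g_k1 * 0.59)
    assert combo.g_kr == pytest.approx(control.g_kr * 0.77)
    assert combo.g_ks == pytest.approx(control.g_ks * 0.42)
    assert combo.eh_shift == pytest.approx(-10.8)
    assert combo.tauh_scale == pytest.approx(2.0)
    # order independence
    other = apply_factors(apply_factors(control, drug_d), hf_d)
    assert other.g_kr == pytest.approx(combo.g_kr)
    assert other.g_na == pytest.approx(combo.g_na)
    assert other.eh_shift == pytest.approx(combo.eh_shift)


def test_compose_with_no_drug_is_identity(control):
    hf = apply_hf(control, g_na_factor=0.61)
    ident = {g: 1.0 for g in ("g_na", "g_cal", "g_kr", "g_ks", "g_k1",
                              "g_to")}
    ident.update(eh_shift=0.0, tauh_scale=1.0)
    combo = compose_hf_drug(factors_of(hf, control), ident, base=control)
    for g in ("g_na", "g_cal", "g_kr", "g_ks", "g_k1", "g_to"):
        assert getattr(combo, g) == pytest.approx(getattr(hf, g))


def test_registry_label_parsing(registry):
    with pytest.raises(KeyError):
        registry.get("am9")
    with pytest.raises(KeyError):
        registry.get("nonsense")
    assert registry.get("control").label == "control"
    assert len(registry.labels()) == 36


def test_params_validation():
    with pytest.raises(ValueError):
        variants.make_control().replace(g_na=-1.0)
    with pytest.raises(ValueError):
        variants.make_control().replace(tauh_scale=0.0)
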