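"""Endpoint mixing-curve predictions for the six cleavage models."""

import numpy as np
import pytest

from marinersim.mechanism_core import MODEL_NAMES, mirror_model
from marinersim.endpoint_predictor import (
    MixCurve,
    closed_form_endpoint,
    mix_curve,
    peak_product,
    predict_endpoint,
    sample_endpoint,
)

MM = [m for m in MODEL_NAMES if m.startswith("mm")]
DD = [m for m in MODEL_NAMES if m.startswith("dd")]
GRID = np.linspace(0.0, 1.0, 101)


@pytest.mark.parametrize("model", MM)
def test_homodimers_only_two_site_models_all_or_nothing(model):
    d = predict_endpoint(model, "homodimers_only", "strict_gate", 0.3)
    assert d.as_dict() == pytest.approx(
        {"SC": 0.3, "N": 0.0, "L": 0.0, "EX": 0.7}, abs=1e-12)


def test_dimer_of_dimers_linear_fraction_closed_form():
    d = predict_endpoint("dd_13_24", "equilibrated", "strict_gate", 0.25)
    assert d["L"] == pytest.approx(27 / 128, abs=1e-12)


def test_single_dimer_heterodimer_intermediate():
    d = predict_endpoint("mm_13_24", "equilibrated", "strict_gate", 0.5)
    assert d.as_dict() == pytest.approx(
        {"SC": 0.25, "N": 0.5, "L": 0.0, "EX": 0.25}, abs=1e-12)


@pytest.mark.parametrize("model", MODEL_NAMES)
@pytest.mark.parametrize("scenario", ["homodimers_only", "equilibrated"])
@pytest.mark.parametrize("ordering", ["strict_gate", "per_end_gate", "none"])
def test_pure_pools_are_trivial_endpoints(model, scenario, ordering):
    assert predict_endpoint(model, scenario, ordering, 0.0)["EX"] == pytest.approx(1.0)
    assert predict_endpoint(model, scenario, ordering, 1.0)["SC"] == pytest.approx(1.0)


@pytest.mark.parametrize("model", MODEL_NAMES)
@pytest.mark.parametrize("scenario", ["homodimers_only", "equilibrated"])
def test_enumeration_matches_closed_forms(model, scenario):
    for f in GRID:
        cf = closed_form_endpoint(model, scenario, "strict_gate", float(f))
        assert cf is not None
        en = predict_endpoint(model, scenario, "strict_gate", float(f))
        assert np.abs(cf.as_array() - en.as_array()).max() < 1e-9


def test_closed_form_examples_and_unavailable_cases():
    assert closed_form_endpoint("mm_12_34", "equilibrated", "strict_gate",
                                0.5)["SC"] == pytest.approx(0.5)
    assert closed_form_endpoint("mm_13_24", "equilibrated", "strict_gate",
                                1.0)["SC"] == pytest.approx(1.0)
    assert closed_form_endpoint("dd_13_24", "equilibrated", "strict_gate",
                                0.25)["L"] == pytest.approx(27 / 128)
    assert closed_form_endpoint("mm_13_24", "equilibrated", "none", 0.5) is None


def _curves_equal(m1, m2, scenario, ordering="strict_gate", grid=GRID):
    a = np.array([predict_endpoint(m1, scenario, ordering, f).as_array()
                  for f in grid])
    b = np.array([predict_endpoint(m2, scenario, ordering, f).as_array()
                  for f in grid])
    return np.abs(a - b).max() < 1e-9


def test_graph_equivalences():
    """The distinguishability pattern of the six models.

    Without pre-equilibration all dimer models coincide; the per-end
    dimer-of-dimers variants coincide in both scenarios; the cis/trans
    single-dimer variants coincide after equilibration; the 5'/3'-split
    variants are the odd ones out in their respective panels.
    """
    # (i) all mm identical under homodimers_only
    assert _curves_equal("mm_13_24", "mm_14_23", "homodimers_only")
    assert _curves_equal("mm_13_24", "mm_12_34", "homodimers_only")
    # (ii) dd_13_24 == dd_14_23 under both scenarios
    for sc in ("homodimers_only", "equilibrated"):
        assert _curves_equal("dd_13_24", "dd_14_23", sc)
    # (iii) mm_13_24 == mm_14_23 under equilibrated
    assert _curves_equal("mm_13_24", "mm_14_23", "equilibrated")
    # (iv) mm_12_34 differs from both on the open interval
    for f in np.linspace(0.05, 0.95, 19):
        a = predict_endpoint("mm_12_34", "equilibrated", "strict_gate", f)
        b = predict_endpoint("mm_13_24", "equilibrated", "strict_gate", f)
        assert np.abs(a.as_array() - b.as_array()).max() > 1e-6
    # (v) dd_12_34 differs from dd_13_24 (no-pre-equilibration panel)
    assert not _curves_equal("dd_12_34", "dd_13_24", "homodimers_only")


@pytest.mark.parametrize("model", MODEL_NAMES)
@pytest.mark.parametrize("scenario", ["homodimers_only", "equilibrated"])
@pytest.mark.parametrize("ordering", ["strict_gate", "per_end_gate", "none"])
def test_substrate_monotone_excision_antitone(model, scenario, ordering):
    curve = mix_curve(model, scenario, ordering, np.linspace(0, 1, 21)).table
    assert np.all(np.diff(curve["SC"]) >= -1e-12)
    assert np.all(np.diff(curve["EX"]) <= 1e-12)


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_end_label_symmetry(model):
    mirrored = mirror_model(model)
    for f in (0.2, 0.5, 0.8):
        a = predict_endpoint(model, "equilibrated", "strict_gate", f)
        b = predict_endpoint(mirrored, "equilibrated", "strict_gate", f)
        assert np.abs(a.as_array() - b.as_array()).max() < 1e-12


def test_homodimers_only_sc_linear_in_f():
    curve = mix_curve("mm_14_23", "homodimers_only", "strict_gate",
                      np.linspace(0, 1, 21)).table
    assert curve["SC"].to_numpy() == pytest.approx(curve["f"].to_numpy(),
                                                   abs=1e-12)


def test_mix_curve_validation():
    with pytest.raises(ValueError):
        mix_curve("mm_13_24", "equilibrated", "strict_gate", [])
    with pytest.raises(ValueError):
        mix_curve("mm_13_24", "equilibrated", "strict_gate", [0.5, 0.2])


def test_peak_product_values():
    grid = np.linspace(0, 1, 21)
    dd = mix_curve("dd_13_24", "equilibrated", "strict_gate", grid)
    f_at, v = peak_product(dd, "L")
    assert f_at == pytest.approx(0.25, abs=1e-6)      # argmax of 2f(1-f)^3
    assert v == pytest.approx(27 / 128, abs=1e-9)
    mm = mix_curve("mm_13_24", "equilibrated", "strict_gate", grid)
    f_at, v = peak_product(mm, "N")
    assert (f_at, v) == pytest.approx((0.5, 0.5), abs=1e-6)
    flat = mix_curve("mm_13_24", "homodimers_only", "strict_gate", grid)
    assert peak_product(flat, "L") == (0.0, 0.0)      # tie-break to smallest f
    with pytest.raises(ValueError):
        peak_product(flat, "BB")


@pytest.mark.parametrize("model,scenario,f", [
    ("mm_13_24", "equilibrated", 0.5),
    ("dd_13_24", "equilibrated", 0.25),
    ("dd_12_34", "homodimers_only", 0.4),
])
def test_monte_carlo_oracle_agreement(model, scenario, f):
    """1e5-complex sampling reproduces the exact enumeration within 4 SE."""
    n = 100_000
    rng = np.random.default_rng(2024)
    mc = sample_endpoint(model, scenario, "strict_gate", f, n, rng).as_array()
    exact = predict_endpoint(model, scenario, "strict_gate", f).as_array()
    se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n)
    assert np.all(np.abs(mc - exact) <= 4 * se + 1e-12)
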