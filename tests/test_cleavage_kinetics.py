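"""Master-equation kinetics of ordered nicking."""

import numpy as np
import pytest
from scipy.linalg import expm

from marinersim.mechanism_core import MODEL_NAMES, get_model
from marinersim.endpoint_predictor import predict_endpoint
from marinersim.cleavage_kinetics import (
    KineticRates,
    expm_timecourse,
    fit_leak,
    generator_matrix,
    simulate_timecourse,
    strand_cleavage_fractions,
)

PRODUCTS = ["SC", "N", "L", "EX"]


def test_rate_validation():
    with pytest.raises(ValueError):
        KineticRates(k5=-1)
    with pytest.raises(ValueError):
        KineticRates(leak=1.5)
    with pytest.raises(ValueError):
        simulate_timecourse("mm_13_24", ["active", "active"],
                            times=[1.0, 0.5])
    with pytest.raises(ValueError):
        simulate_timecourse("mm_13_24", ["active"], times=[0, 1])


def test_wild_type_completes_excision():
    tc = simulate_timecourse("mm_13_24", ["active", "active"],
                             rates=KineticRates(), times=[0.0, 50.0])
    assert tc.table.iloc[0]["SC"] == pytest.approx(1.0)
    assert tc.table.iloc[-1]["EX"] == pytest.approx(1.0, abs=1e-9)


def test_probability_conserved_each_step():
    tc = simulate_timecourse("dd_13_24", scenario="equilibrated", f=0.4,
                             rates=KineticRates(leak=0.2),
                             times=np.linspace(0, 4, 17))
    sums = tc.table[PRODUCTS].sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-8


def test_heterodimer_nicked_intermediate_rises_then_falls():
    """One dead subunit in the cis dimer model: the open-circular
    intermediate accumulates, then leaks slowly into linear, which
    reaches 100% at long times (SC -> N -> L chain)."""
    rates = KineticRates(k5=3.0, k3=3.0, leak=0.1)
    t = np.linspace(0.0, 200.0, 401)
    tc = simulate_timecourse("mm_13_24", ["active", "dead"], rates=rates,
                             times=t)
    n = tc.table["N"].to_numpy()
    peak = int(np.argmax(n))
    assert 0 < peak < len(n) - 1
    assert n[peak] > 0.5
    assert tc.table.iloc[-1]["L"] == pytest.approx(1.0, abs=1e-6)
    # independent oracle: 3-state chain SC -> N -> L with rates k5, leak*k3
    Q = np.array([[-3.0, 0.0, 0.0], [3.0, -0.3, 0.0], [0.0, 0.3, 0.0]])
    for i in (10, 100, 300):
        p = expm(Q * t[i]) @ np.array([1.0, 0.0, 0.0])
        row = tc.table.iloc[i]
        assert row["SC"] == pytest.approx(p[0], abs=1e-7)
        assert row["N"] == pytest.approx(p[1], abs=1e-7)
        assert row["L"] == pytest.approx(p[2], abs=1e-7)


def test_trans_heterodimer_never_linearises():
    """With the trans model, the live subunit's 3' nick sits at the end
    whose 5' nick the dead subunit owns; the local requirement makes the
    linear product unreachable."""
    tc = simulate_timecourse("mm_14_23", ["active", "dead"],
                             rates=KineticRates(leak=0.8), times=np.linspace(0, 100, 51))
    assert np.abs(tc.table["L"]).max() == 0.0
    # reachability oracle: no transition chain reaches an end-severing state
    m = get_model("mm_14_23")
    Q = generator_matrix(m, (True, False), KineticRates(leak=0.8))
    reachable = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(Q[:, i] > 0):
            if j not in reachable:
                reachable.add(int(j))
                frontier.append(int(j))
    from marinersim.cleavage_kinetics import _STATE_CLASS
    assert all(_STATE_CLASS[j] != PRODUCTS.index("L") for j in reachable)


@pytest.mark.parametrize("leak,local,ordering", [
    (0.0, True, "strict_gate"),
    (1.0, True, "per_end_gate"),
    (1.0, False, "none"),
])
def test_kinetic_endpoints_match_endpoint_predictor(leak, local, ordering):
    """t->inf limits reproduce the endpoint enumeration for the matching
    ordering rule, across all six models and 11 mutant fractions."""
    rates = KineticRates(k5=3.0, k3=3.0, leak=leak, local_requirement=local)
    for model in MODEL_NAMES:
        for f in np.linspace(0.0, 1.0, 11):
            tc = expm_timecourse(model, scenario="equilibrated", f=float(f),
                                 rates=rates, times=[500.0])
            kin = tc.table.iloc[-1][PRODUCTS].to_numpy(dtype=float)
            ep = predict_endpoint(model, "equilibrated", ordering,
                                  float(f)).as_array()
            assert np.abs(kin - ep).max() < 1e-8, (model, f)


def test_adaptive_integration_matches_matrix_exponential():
    rng = np.random.default_rng(7)
    times = np.linspace(0.0, 4.0, 9)
    for _ in range(5):
        rates = KineticRates(k5=float(rng.uniform(0.5, 5)),
                             k3=float(rng.uniform(0.5, 5)),
                             leak=float(rng.uniform(0, 1)),
                             k_ex_int=float(rng.uniform(0.2, 2)))
        states = rng.choice(["active", "dead"], size=4).tolist()
        a = simulate_timecourse("dd_14_23", states, rates=rates, times=times)
        b = expm_timecourse("dd_14_23", states, rates=rates, times=times)
        diff = np.abs(a.table[PRODUCTS].to_numpy()
                      - b.table[PRODUCTS].to_numpy()).max()
        assert diff < 1e-6


def test_strand_cleavage_fraction_ordering():
    rates = KineticRates(k5=5.0, k3=0.5, leak=0.1)
    tc = simulate_timecourse("mm_13_24", ["active", "active"], rates=rates,
                             times=np.linspace(0, 3, 31))
    sf = strand_cleavage_fractions(tc)
    assert sf.iloc[0][["frac_5p_nicked", "frac_3p_nicked"]].to_numpy() == \
        pytest.approx([0.0, 0.0])
    # with the local requirement, 5'-nicked molecules always lead
    assert np.all(sf["frac_5p_nicked"] >= sf["frac_3p_nicked"] - 1e-12)
    # k5 >> k3: the 5' wave visibly precedes the 3' wave
    assert sf.iloc[5]["frac_5p_nicked"] > sf.iloc[5]["frac_3p_nicked"] + 0.1


def test_mutant_three_prime_nicking_delayed_vs_wild_type():
    rates = KineticRates(k5=3.0, k3=3.0, leak=0.05)
    times = np.linspace(0.25, 4.0, 16)
    wt = strand_cleavage_fractions(
        simulate_timecourse("mm_13_24", ["active", "active"], rates=rates,
                            times=times))
    het = strand_cleavage_fractions(
        simulate_timecourse("mm_13_24", ["active", "dead"], rates=rates,
                            times=times))
    assert np.all(het["frac_3p_nicked"].to_numpy()
                  < wt["frac_3p_nicked"].to_numpy())


def test_fit_leak_recovers_truth_on_clean_data():
    truth = KineticRates(k5=3.0, k3=3.0, leak=0.1)
    times = np.linspace(0, 4, 9)
    tc = simulate_timecourse("mm_13_24", ["active", "dead"], rates=truth,
                             times=times)
    est = fit_leak(tc.table, "mm_13_24", ["active", "dead"], truth,
                   leak_grid=np.geomspace(0.01, 1.0, 30))
    assert 0.5 * 0.1 <= est <= 2 * 0.1
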