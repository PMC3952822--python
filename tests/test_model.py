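"""Core ODE system: rate laws, steady states, balances and sweep directions."""

import numpy as np
import pytest

import rctsim
from rctsim import (DEFAULT_INITIAL_STATE, ModelConstants, ParameterSet,
                    RctModel, StateVector)

C = ModelConstants()


def test_parameter_set_round_trip_and_validation(posterior):
    arr = posterior.to_array()
    assert ParameterSet.from_array(arr) == posterior
    assert len(arr) == 16
    with pytest.raises(ValueError):
        ParameterSet.from_array(np.append(arr[:-1], np.nan))
    with pytest.raises(ValueError):
        posterior.scaled(k_kidney=-1.0)
    # ku1 is the one parameter allowed to be negative
    assert posterior.ku1 < 0


def test_holo_uptake_rate(model, posterior):
    flat = posterior.scaled(ku1=0.0)
    assert model.holo_uptake_rate(80.0, flat) == pytest.approx(flat.ku0)
    assert model.holo_uptake_rate(130.0, flat) == pytest.approx(flat.ku0)
    # arithmetic: u = 0.13 - 0.016 (9.77 - 7.5)
    u = model.holo_uptake_rate(97.7, posterior)
    assert u == pytest.approx(0.13 - 0.016 * (9.77 - 7.5), abs=1e-12)
    # decreasing in size for a negative slope
    assert (model.holo_uptake_rate(110.0, posterior)
            < model.holo_uptake_rate(90.0, posterior))


def test_fusion_fraction_saturates(model, posterior):
    assert model.fusion_fraction(0.0, posterior) == 0.0
    ps = np.logspace(-5, -1, 30)
    phis = np.array([model.fusion_fraction(p, posterior) for p in ps])
    assert np.all(np.diff(phis) > 0)
    assert np.all((phis >= 0) & (phis < 1))
    assert phis[-1] > 0.999


def test_zero_state_is_fixed_point_without_synthesis(model, posterior):
    p = posterior.scaled(s_apoa1=0.0, s_vldl_ce=0.0)
    assert np.allclose(model.rhs(np.zeros(6), p), 0.0)


def test_rhs_rejects_nan_state(model, posterior):
    with pytest.raises(ValueError):
        model.rhs(np.array([np.nan, 1, 1e-3, 1, 1, 1]), posterior)


def test_cetp_null_apob_pools_match_closed_form(model, posterior):
    """With the CETP transfers off, the VLDL/LDL CE subsystem is linear and
    solvable by hand."""
    p = posterior.scaled(k_hv=0.0, k_hl=0.0, k_lh=0.0)
    ss = model.steady_state(p)
    vldl = p.s_vldl_ce / (p.k_vl + p.k_ev)
    assert ss.ce_vldl == pytest.approx(vldl, rel=1e-9)
    assert ss.ce_ldl == pytest.approx(p.k_vl * vldl / p.k_el, rel=1e-9)


def test_steady_state_is_stationary_and_deterministic(model, posterior,
                                                      nominal_steady):
    y = nominal_steady.to_array()
    resid = model.rhs(y, posterior)
    assert np.linalg.norm(resid) / np.linalg.norm(y) < 1e-10
    again = model.steady_state(posterior)
    assert np.array_equal(again.to_array(), y)


def test_apoa1_mass_balance_at_steady_state(model, posterior, nominal_steady):
    """Synthesis equals kidney elimination plus holo-uptake of the alpha pool."""
    out = model.derived_outputs(nominal_steady, posterior)
    d = out.hdl_size * 10.0
    u = model.holo_uptake_rate(d, posterior)
    lhs = posterior.s_apoa1
    rhs = posterior.k_kidney * nominal_steady.a_lp + u * nominal_steady.a_alpha
    assert rhs == pytest.approx(lhs, rel=1e-8)


def test_ce_mass_balance_at_steady_state(model, posterior, nominal_steady):
    """RCT input plus VLDL-CE synthesis equals total CE elimination; the
    CETP transfer terms cancel among the three pools."""
    s = nominal_steady
    out = model.derived_outputs(s, posterior)
    u = model.holo_uptake_rate(out.hdl_size * 10.0, posterior)
    influx = (posterior.gamma * (C.mw_chol / C.mw_apoa1)
              * posterior.k_abca1 * s.a_lp + posterior.s_vldl_ce)
    efflux = ((posterior.k_srb1 + u) * s.ce_hdl
              + posterior.k_ev * s.ce_vldl + posterior.k_el * s.ce_ldl)
    assert efflux == pytest.approx(influx, rel=1e-8)


def test_lipid_poor_steady_state_identity(model, posterior, nominal_steady):
    """a_lp = (s + k_diss X) / (k_abca1 + k_kidney) at equilibrium."""
    s = nominal_steady
    x = rctsim.excess_apoa1_conc(s.a_alpha, s.ce_hdl, s.p_hdl,
                                 model.surface, model.constants)
    expected = ((posterior.s_apoa1 + posterior.k_diss * x)
                / (posterior.k_abca1 + posterior.k_kidney))
    assert s.a_lp == pytest.approx(expected, rel=1e-8)


def test_hdl_ce_clearance_identity(model, posterior, nominal_steady):
    """At equilibrium HDL-CE equals its input rate (RCT plus CETP back
    transfer) divided by the clearance, expressed at the whole-body level."""
    s = nominal_steady
    out = model.derived_outputs(s, posterior)
    input_rate = (out.rct_rate
                  + posterior.k_lh * s.ce_ldl * C.plasma_volume * 10.0)
    assert s.ce_hdl == pytest.approx(input_rate / (10.0 * out.hdl_ce_clearance),
                                     rel=1e-8)


def test_rct_rate_arithmetic_and_linearity(model, posterior):
    state = StateVector(6.0, 120.0, 1.4e-3, 35.0, 80.0, 5.0)
    k = posterior
    expected = 10.17 * (386.0 / 28500.0) * 95.18 * 6.0 * 31.5
    assert model.rct_rate(state, k) == pytest.approx(expected, rel=1e-3)
    assert model.rct_rate(state, k.scaled(gamma=2.0)) == pytest.approx(
        2 * model.rct_rate(state, k))
    zero = StateVector(0.0, 120.0, 1.4e-3, 35.0, 80.0, 5.0)
    assert model.rct_rate(zero, k) == 0.0


def test_derived_outputs_fractions(model, posterior):
    state = StateVector(5.0, 95.0, 1.4e-3, 35.0, 80.0, 5.0)
    out = model.derived_outputs(state, posterior)
    assert out.frac_lipid_poor == pytest.approx(5.0)
    assert out.hdl_c >= state.ce_hdl
    assert out.ldl_c == pytest.approx(80.0 / 0.7)


def test_fcr_equals_turnover_at_steady_state(model, posterior, nominal_steady):
    out = model.derived_outputs(nominal_steady, posterior)
    assert out.fcr_apoa1 == pytest.approx(
        posterior.s_apoa1 / out.apoa1_total, rel=1e-8)


def test_trajectories_remain_nonnegative(model, posterior):
    """Non-negativity from perturbed non-negative states across random
    parameter draws."""
    rng = np.random.default_rng(7)
    base = posterior.to_array()
    for _ in range(5):
        draw = base * (1 + 0.15 * rng.standard_normal(16))
        draw = np.where(np.sign(draw) == np.sign(base), draw, base)
        p = ParameterSet.from_array(draw)
        y0 = DEFAULT_INITIAL_STATE.to_array() * rng.uniform(0.2, 2.0, 6)
        sol = model.integrate(p, (0.0, 200.0), y0,
                              t_eval=np.linspace(0, 200, 101))
        assert sol.y.min() > -1e-9


def test_cetp_inhibition_sweep_directions(model, posterior):
    """Lowering CETP activity raises HDL-C, ApoA-I and particle size while
    leaving the RCT rate essentially unchanged (<2%)."""
    scales = np.linspace(1.0, 0.0, 6)
    rows = []
    init = None
    for s in scales:
        p = posterior.scaled(k_hv=s, k_hl=s, k_lh=s)
        ss = model.steady_state(p, init=init, fast=init is not None)
        init = ss
        rows.append(model.derived_outputs(ss, p))
    hdl_c = [r.hdl_c for r in rows]
    apoa1 = [r.apoa1_total for r in rows]
    size = [r.hdl_size for r in rows]
    rct = np.array([r.rct_rate for r in rows])
    assert np.all(np.diff(hdl_c) > 0)
    assert np.all(np.diff(apoa1) > 0)
    assert np.all(np.diff(size) > 0)
    assert np.max(np.abs(rct / rct[0] - 1.0)) < 0.02


def test_abca1_upregulation_sweep_directions(model, posterior):
    """Raising ABCA1 activity increases RCT, HDL-C, HDL-P and LDL-C and
    depletes lipid-poor ApoA-I."""
    rows = []
    init = None
    for s in np.linspace(1.0, 3.0, 6):
        p = posterior.scaled(k_abca1=s)
        ss = model.steady_state(p, init=init, fast=init is not None)
        init = ss
        out = model.derived_outputs(ss, p)
        rows.append((out.rct_rate, out.hdl_c, out.hdl_p, out.ldl_c, ss.a_lp))
    arr = np.array(rows)
    for col in range(4):
        assert np.all(np.diff(arr[:, col]) > 0)
    assert np.all(np.diff(arr[:, 4]) < 0)


def test_fcr_decreases_with_size_across_cetp_scalings(model, posterior):
    """Across CETP activity levels the ApoA-I FCR falls as the HDL-C/ApoA-I
    ratio (size surrogate) grows."""
    ratios, fcrs = [], []
    for s in (1.0, 0.75, 0.5, 0.25, 0.0):
        p = posterior.scaled(k_hv=s, k_hl=s, k_lh=s)
        out = model.derived_outputs(model.steady_state(p), p)
        ratios.append(out.hdl_c / out.apoa1_total)
        fcrs.append(out.fcr_apoa1)
    order = np.argsort(ratios)
    assert np.all(np.diff(np.array(fcrs)[order]) < 0)


def test_degenerate_abca1_null_pool(model, posterior):
    """Tangier-like parameters: the particle pool empties and lipid-poor
    ApoA-I settles at synthesis over kidney clearance."""
    p = posterior.scaled(k_abca1=0.0)
    ss = model.steady_state(p)
    assert ss.a_lp == pytest.approx(p.s_apoa1 / p.k_kidney, rel=1e-6)
    assert ss.p_hdl < 1e-5
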