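"""MAP calibration: objective structure, fitting, information and confidence."""

import numpy as np
import pytest

import rctsim
from rctsim import (CalibrationConfig, ParameterSet, chi2_delta, confidence_set,
                    fcr_target, fit_map, load_fixtures, map_objective,
                    posterior_sd_fim, simulate_observables)
from rctsim.calibration import OBSERVABLE_LABELS, _residual_vector
from rctsim.fixtures import CalibrationDataset, FcrRelation


def test_fcr_target_piecewise_linear():
    rel = FcrRelation(slope=-0.2, intercept=0.3, floor=0.135, sd_band=0.065)
    assert fcr_target(100.0, rel) == 0.135       # very large ratio hits floor
    flat = FcrRelation(slope=0.0, intercept=0.2)
    assert fcr_target(0.1, flat) == fcr_target(5.0, flat) == 0.2
    ratios = np.linspace(0.1, 2.0, 20)
    vals = [fcr_target(r, rel) for r in ratios]
    assert np.all(np.diff(vals) <= 0)
    with pytest.raises(ValueError):
        fcr_target(0.0, rel)


def test_observables_cover_all_scenarios(posterior, model):
    g, preds = simulate_observables(posterior, model)
    assert g.shape == (15,)
    assert np.all(np.isfinite(g))
    # homozygote scenario uses exactly zero CETP activity: its LDL-CE matches
    # the closed-form CETP-null subsystem
    p0 = posterior.scaled(k_hv=0.0, k_hl=0.0, k_lh=0.0)
    vldl = p0.s_vldl_ce / (p0.k_vl + p0.k_ev)
    assert preds["vldl_ce:cetp_hom"] == pytest.approx(vldl, rel=1e-9)


def test_nominal_predictions_match_pooled_observables(posterior, model):
    """At the nominal parameter estimates the model reproduces the pooled
    normal-subject HDL-C and ApoA-I within 10%."""
    _, preds = simulate_observables(posterior, model)
    assert preds["hdl_c:normal"] == pytest.approx(52.0, rel=0.10)
    assert preds["apoa1:normal"] == pytest.approx(139.0, rel=0.10)


def test_cetp_ce_fluxes_nearly_balanced(posterior, model):
    """The CE flux HDL->LDL is close to the reverse LDL->HDL flux."""
    _, preds = simulate_observables(posterior, model)
    fwd, back = preds["flux:hdl_to_ldl"], preds["flux:ldl_to_hdl"]
    assert abs(fwd - back) / fwd < 0.25


def test_objective_scaling_and_order_invariance(posterior):
    data = load_fixtures("calibration")
    prior = load_fixtures("prior")
    model = rctsim.RctModel()
    r = _residual_vector(posterior, data, prior, model)
    j = float(r @ r)
    assert map_objective(posterior, data, prior, model) == pytest.approx(j)
    # scaling every data uncertainty by c scales the data term by 1/c^2
    c = 2.0
    rel = data.fcr_relation
    scaled = CalibrationDataset(
        observables=tuple((s, q, v, c * sem) for s, q, v, sem in data.observables),
        ce_fluxes=tuple((f, v, c * sem) for f, v, sem in data.ce_fluxes),
        fcr_relation=FcrRelation(rel.slope, rel.intercept, rel.floor,
                                 c * rel.sd_band))
    r_scaled = _residual_vector(posterior, scaled, prior, model)
    n_data = 15
    assert float(r_scaled[:n_data] @ r_scaled[:n_data]) == pytest.approx(
        float(r[:n_data] @ r[:n_data]) / c**2, rel=1e-9)
    # residual ordering of the dataset does not change the objective
    shuffled = CalibrationDataset(observables=data.observables[::-1],
                                  ce_fluxes=data.ce_fluxes[::-1],
                                  fcr_relation=rel)
    assert map_objective(posterior, shuffled, prior, model) == pytest.approx(j)


def test_prior_term_unit_increment(posterior):
    """Moving one informative parameter by +1 prior SD adds one unit to the
    prior part of the objective."""
    prior = load_fixtures("prior")
    data = load_fixtures("calibration")
    model = rctsim.RctModel()

    def prior_term(k: ParameterSet) -> float:
        r = _residual_vector(k, data, prior, model)
        return float(r[15:] @ r[15:])

    base = prior_term(posterior)
    i = list(rctsim.PARAMETER_NAMES).index("k_vl")
    bumped = posterior.scaled(k_vl=(prior.means[i] + prior.sds[i])
                              / posterior.k_vl)
    # relative to the prior mean the bumped parameter sits exactly 1 SD away
    delta = prior_term(bumped) - base
    expected = 1.0 - ((posterior.k_vl - prior.means[i]) / prior.sds[i]) ** 2
    assert delta == pytest.approx(expected, rel=1e-9)


def test_map_fit_dominates_nominal_estimates(map_result, posterior):
    j_nominal = map_objective(posterior)
    assert map_result.objective <= j_nominal
    assert map_result.converged


def test_parameter_recovery_within_confidence_region(posterior, model):
    """Fitting synthetic data generated from a known parameter set recovers
    it within the chi-square confidence region of the fit."""
    rng = np.random.default_rng(11)
    truth = posterior
    g, preds = simulate_observables(truth, model)
    data = load_fixtures("calibration")
    sems = {lab: sem for (s, q, v, sem), lab in zip(
        data.observables, OBSERVABLE_LABELS[:9])}
    sems.update({f"flux:{f}": sem for f, v, sem in data.ce_fluxes})
    obs, fluxes = [], []
    for lab, value in zip(OBSERVABLE_LABELS[:9], g[:9]):
        quantity, scen = lab.split(":")
        sem = sems[lab]
        obs.append((scen, quantity, value + sem * rng.standard_normal(), sem))
    for lab, value in zip(OBSERVABLE_LABELS[9:12], g[9:12]):
        sem = sems[lab]
        fluxes.append((lab.split(":")[1],
                       value + sem * rng.standard_normal(), sem))
    synth = CalibrationDataset(observables=tuple(obs), ce_fluxes=tuple(fluxes))

    result = fit_map(data=synth, config=CalibrationConfig(local_max_nfev=60),
                     start=truth.scaled(gamma=1.1, k_srb1=0.9, k_hl=1.1))
    j_truth = map_objective(truth, synth)
    assert j_truth - result.objective <= chi2_delta(29, 0.95)
    assert result.objective <= j_truth + 1e-9


def test_posterior_sd_information_monotonicity(posterior):
    """Calibration data can only sharpen informative priors: every posterior
    SD stays at or below its prior SD (to jacobian tolerance)."""
    prior = load_fixtures("prior")
    sds = posterior_sd_fim(posterior)
    inf = prior.informative
    assert np.all(sds[inf] <= prior.sds[inf] * 1.001)
    # the two prior-free parameters become identifiable from the data alone
    assert np.all(np.isfinite(sds[~inf]))


def test_confidence_set_contains_map_and_respects_threshold(posterior):
    cfg = CalibrationConfig(n_confidence_samples=25, seed=5)
    members = confidence_set(posterior, cfg)
    assert len(members) == 25
    assert members[0] == posterior
    delta = chi2_delta(cfg.df, cfg.confidence_level)
    j0 = map_objective(posterior)
    worst = max(map_objective(k) for k in members[1:5])
    assert worst - j0 <= delta + 1e-6


@pytest.fixture(scope="session")
def map_result():
    return fit_map(config=CalibrationConfig(local_max_nfev=60))
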