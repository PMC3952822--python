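"""Bayesian MAP calibration of the model to pooled literature observables.

The objective is the standard Gaussian MAP form

    J(k) = (g(k) - d)^T C_D^-1 (g(k) - d)  +  (k - k0)^T C_M^-1 (k - k0)

with diagonal covariances: C_D from the squared SEMs of the calibration data
and C_M from the squared prior SDs, parameters without an informative prior
contributing zero precision.  The 15 data residuals are: HDL-C and total
ApoA-I for the nominal subject and for CETP-deficiency heterozygotes (50%
CETP activity) and homozygotes (0%); LDL-CE and VLDL-CE for the nominal
subject and LDL-CE for heterozygotes; the three CE fluxes (HDL->VLDL,
HDL->LDL, LDL->HDL); and the ApoA-I FCR at the three scenarios, whose target
is the piecewise-linear FCR-versus-size relation evaluated at the predicted
HDL-C/ApoA-I ratio.

Posterior spreads are estimated from the Fisher information of the weighted
residual map, and confidence sets by sampling parameters whose objective
excess over the MAP stays within the chi-square quantile for the residual
degrees of freedom (15 data + 14 informative-prior terms = 29).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .fixtures import (SCENARIO_CETP_SCALE, SCENARIOS, CalibrationDataset,
                       PriorSpec, load_fixtures)
from .model import PARAMETER_NAMES, ParameterSet, RctModel, SteadyStateError

__all__ = [
    "CalibrationConfig",
    "PosteriorResult",
    "OBSERVABLE_LABELS",
    "simulate_observables",
    "fcr_target",
    "map_objective",
    "fit_map",
    "posterior_sd_fim",
    "confidence_set",
    "chi2_delta",
]

#: Labels of the 15-entry prediction vector, in order.
OBSERVABLE_LABELS = (
    "hdl_c:normal", "apoa1:normal",
    "hdl_c:cetp_het", "apoa1:cetp_het",
    "hdl_c:cetp_hom", "apoa1:cetp_hom",
    "ldl_ce:normal", "vldl_ce:normal", "ldl_ce:cetp_het",
    "flux:hdl_to_vldl", "flux:hdl_to_ldl", "flux:ldl_to_hdl",
    "fcr:normal", "fcr:cetp_het", "fcr:cetp_hom",
)

#: Residual degrees of freedom: 15 data + 14 informative-prior terms.
DEFAULT_DF = 29

_LARGE_PENALTY = 1e8


@dataclass(frozen=True)
class CalibrationConfig:
    """Optimizer and confidence-set settings.

    The global stage is a differential-evolution search within prior-scaled
    bounds; the local stage a trust-region least-squares polish.  The default
    budgets are deliberately modest (the objective is smooth and the priors
    informative); raise them for production refits.
    """

    global_popsize: int = 12
    global_maxiter: int = 25
    local_max_nfev: int = 400
    use_global: bool = False
    seed: int = 0
    df: int = DEFAULT_DF
    confidence_level: float = 0.95
    n_confidence_samples: int = 1000


@dataclass(frozen=True)
class PosteriorResult:
    """MAP estimate with its objective value and FIM-based posterior SDs."""

    k_map: ParameterSet
    objective: float
    posterior_sd: np.ndarray
    n_evaluations: int
    converged: bool
    trace: tuple = field(default=(), repr=False)


def fcr_target(ratio: float, relation) -> float:
    """Target ApoA-I FCR (pool/day) at a given HDL-C/ApoA-I ratio."""
    if ratio <= 0:
        raise ValueError(f"HDL-C/ApoA-I ratio must be positive, got {ratio}")
    return relation(ratio)


def simulate_observables(params: ParameterSet, model: RctModel | None = None,
                         warm: dict | None = None) -> tuple[np.ndarray, dict]:
    """Steady-state predictions of the 15 calibration observables.

    CETP scenarios scale the three CETP transfer constants together; the
    homozygote uses exactly zero.  CE fluxes are first-order products of the
    nominal-subject steady state, in mg/dL/day.  Returns the 15-vector in
    ``OBSERVABLE_LABELS`` order together with a dict of named predictions.
    ``warm`` may hold per-scenario starting states (updated in place) to
    accelerate repeated evaluations during optimization.
    """
    model = model or RctModel()
    preds = {}
    for scen in SCENARIOS:
        scale = SCENARIO_CETP_SCALE[scen]
        p = params.scaled(k_hv=scale, k_hl=scale, k_lh=scale)
        try:
            if warm is not None and scen in warm:
                ss = model.steady_state(p, init=warm[scen], fast=True)
            else:
                ss = model.steady_state(p)
            if warm is not None:
                warm[scen] = ss
        except SteadyStateError as err:
            raise SteadyStateError(
                f"steady state failed for calibration scenario {scen!r}: {err}",
                state=err.state, residual=err.residual)
        out = model.derived_outputs(ss, p)
        preds[f"hdl_c:{scen}"] = out.hdl_c
        preds[f"apoa1:{scen}"] = out.apoa1_total
        preds[f"fcr:{scen}"] = out.fcr_apoa1
        preds[f"ratio:{scen}"] = out.hdl_c / out.apoa1_total
        preds[f"ldl_ce:{scen}"] = ss.ce_ldl
        preds[f"vldl_ce:{scen}"] = ss.ce_vldl
        if scen == "normal":
            preds["flux:hdl_to_vldl"] = params.k_hv * ss.ce_hdl
            preds["flux:hdl_to_ldl"] = params.k_hl * ss.ce_hdl
            preds["flux:ldl_to_hdl"] = params.k_lh * ss.ce_ldl
    return np.array([preds[lab] for lab in OBSERVABLE_LABELS]), preds


def _residual_vector(params: ParameterSet, data: CalibrationDataset,
                     prior: PriorSpec, model: RctModel,
                     warm: dict | None = None) -> np.ndarray:
    """Weighted residuals (data then prior rows); J(k) is their squared norm."""
    g, preds = simulate_observables(params, model, warm=warm)
    targets, sems = [], []
    for scen, quantity, value, sem in data.observables:
        targets.append((f"{quantity}:{scen}", value, sem))
    for flux, value, sem in data.ce_fluxes:
        targets.append((f"flux:{flux}", value, sem))
    for scen in SCENARIOS:
        ratio = preds[f"ratio:{scen}"]
        targets.append((f"fcr:{scen}", fcr_target(ratio, data.fcr_relation),
                        data.fcr_relation.sd_band))
    lookup = {lab: (value, sem) for lab, value, sem in targets}
    res_data = np.array([(g[i] - lookup[lab][0]) / lookup[lab][1]
                         for i, lab in enumerate(OBSERVABLE_LABELS)])
    k = params.to_array()
    res_prior = np.where(prior.informative,
                         (k - prior.means) / np.where(prior.informative,
                                                      prior.sds, 1.0),
                         0.0)
    return np.concatenate([res_data, res_prior[prior.informative]])


def map_objective(params: ParameterSet, data: CalibrationDataset | None = None,
                  prior: PriorSpec | None = None,
                  model: RctModel | None = None) -> float:
    """MAP objective J(k); returns a large penalty if predictions fail."""
    data = data or load_fixtures("calibration")
    prior = prior or load_fixtures("prior")
    model = model or RctModel()
    try:
        r = _residual_vector(params, data, prior, model)
    except (SteadyStateError, ValueError, FloatingPointError):
        return _LARGE_PENALTY
    if not np.all(np.isfinite(r)):
        return _LARGE_PENALTY
    return float(r @ r)


def _bounds(prior: PriorSpec) -> list[tuple[float, float]]:
    """Search bounds: several prior SDs around informative means, wide
    positive ranges for the two free parameters (sign of the uptake slope
    left free)."""
    lo, hi = [], []
    for i, name in enumerate(PARAMETER_NAMES):
        if prior.informative[i]:
            m, s = prior.means[i], prior.sds[i]
            lower = max(0.0, m - 4 * s) if name != "ku1" else m - 4 * s
            lo.append(lower)
            hi.append(m + 4 * s)
        elif name == "ku1":
            lo.append(-0.1)
            hi.append(0.1)
        elif name == "k_fus":
            lo.append(0.0)
            hi.append(2e4)
        else:  # pragma: no cover - all free parameters enumerated above
            lo.append(0.0)
            hi.append(10 * abs(prior.means[i]) + 1.0)
    return list(zip(lo, hi))


def fit_map(data: CalibrationDataset | None = None,
            prior: PriorSpec | None = None,
            config: CalibrationConfig = CalibrationConfig(),
            model: RctModel | None = None,
            start: ParameterSet | None = None) -> PosteriorResult:
    """Find the MAP parameter set.

    An optional global differential-evolution stage (seeded, within
    prior-derived bounds) precedes a least-squares polish.  By default only
    the local stage runs, started from ``start`` (or, failing that, the
    posterior fixture when the two non-prior parameters need a non-zero
    starting point).
    """
    data = data or load_fixtures("calibration")
    prior = prior or load_fixtures("prior")
    model = model or RctModel()
    bounds = _bounds(prior)
    n_eval = [0]
    trace: list[float] = []
    warm: dict = {}

    def objective_arr(x: np.ndarray) -> float:
        n_eval[0] += 1
        try:
            r = _residual_vector(ParameterSet.from_array(np.maximum(
                x, [b[0] for b in bounds])), data, prior, model, warm)
        except (SteadyStateError, ValueError, FloatingPointError):
            return _LARGE_PENALTY
        if not np.all(np.isfinite(r)):
            return _LARGE_PENALTY
        val = float(r @ r)
        trace.append(val)
        return val

    if start is None:
        start = load_fixtures("posterior_nominal")
    x0 = np.clip(start.to_array(), [b[0] for b in bounds], [b[1] for b in bounds])

    if config.use_global:
        de = optimize.differential_evolution(
            objective_arr, bounds, seed=config.seed,
            popsize=config.global_popsize, maxiter=config.global_maxiter,
            init="sobol", x0=x0, polish=False, tol=1e-8)
        x0 = de.x

    def residuals(x: np.ndarray) -> np.ndarray:
        n_eval[0] += 1
        try:
            r = _residual_vector(ParameterSet.from_array(x), data, prior,
                                 model, warm)
        except (SteadyStateError, ValueError, FloatingPointError):
            return np.full(15 + prior.n_informative, 1e4)
        r = np.where(np.isfinite(r), r, 1e4)
        trace.append(float(r @ r))
        return r

    ls = optimize.least_squares(
        residuals, x0, bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
        max_nfev=config.local_max_nfev, x_scale="jac", ftol=1e-12, xtol=1e-12)
    k_map = ParameterSet.from_array(ls.x)
    obj = float(ls.cost * 2.0)  # least_squares cost is 0.5 * sum r^2
    try:
        sds = posterior_sd_fim(k_map, data, prior, model)
    except np.linalg.LinAlgError:
        sds = np.full(len(PARAMETER_NAMES), np.nan)
    return PosteriorResult(k_map=k_map, objective=obj, posterior_sd=sds,
                           n_evaluations=n_eval[0], converged=bool(ls.success),
                           trace=tuple(trace))


def _weighted_jacobian(k_map: ParameterSet, data, prior, model,
                       rel_step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Jacobian of the weighted residual vector."""
    x = k_map.to_array()
    r0 = _residual_vector(k_map, data, prior, model)
    J = np.zeros((len(r0), len(x)))
    for i in range(len(x)):
        h = rel_step * max(abs(x[i]), 1e-3)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        rp = _residual_vector(ParameterSet.from_array(xp), data, prior, model)
        rm = _residual_vector(ParameterSet.from_array(xm), data, prior, model)
        J[:, i] = (rp - rm) / (2 * h)
    return J


def posterior_sd_fim(k_map: ParameterSet, data: CalibrationDataset | None = None,
                     prior: PriorSpec | None = None,
                     model: RctModel | None = None) -> np.ndarray:
    """Posterior SDs from the Fisher information of the weighted residuals.

    With r(k) the weighted residual vector (data and prior rows), the
    information matrix is J^T J = G^T C_D^-1 G + C_M^-1 and the posterior
    covariance its inverse.  Raises ``LinAlgError`` naming the most
    non-identifiable parameter direction if the information is singular.
    """
    data = data or load_fixtures("calibration")
    prior = prior or load_fixtures("prior")
    model = model or RctModel()
    J = _weighted_jacobian(k_map, data, prior, model)
    info = J.T @ J
    w, v = np.linalg.eigh(info)
    if w[0] <= max(1e-12, 1e-15 * w[-1]):
        worst = PARAMETER_NAMES[int(np.argmax(np.abs(v[:, 0])))]
        raise np.linalg.LinAlgError(
            f"singular information matrix; weakest direction dominated by {worst}")
    cov = v @ np.diag(1.0 / w) @ v.T
    return np.sqrt(np.diag(cov))


def chi2_delta(df: int = DEFAULT_DF, level: float = 0.95) -> float:
    """Chi-square quantile defining the confidence-set threshold."""
    return float(stats.chi2.ppf(level, df))


def confidence_set(k_map: ParameterSet, config: CalibrationConfig = CalibrationConfig(),
                   data: CalibrationDataset | None = None,
                   prior: PriorSpec | None = None,
                   model: RctModel | None = None,
                   proposal_scale: float = 0.6,
                   rng=None) -> list[ParameterSet]:
    """Sample parameter sets within the objective confidence region.

    Proposals are Gaussian around the MAP with the FIM covariance scaled by
    ``proposal_scale``; points with J(k) - J(k_map) <= chi2(level, df) are
    kept until ``n_confidence_samples`` are collected.  The MAP itself is
    always the first member.
    """
    data = data or load_fixtures("calibration")
    prior = prior or load_fixtures("prior")
    model = model or RctModel()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    delta = chi2_delta(config.df, config.confidence_level)
    warm: dict = {}

    def objective(k: ParameterSet) -> float:
        try:
            r = _residual_vector(k, data, prior, model, warm)
        except (SteadyStateError, ValueError, FloatingPointError):
            return _LARGE_PENALTY
        if not np.all(np.isfinite(r)):
            return _LARGE_PENALTY
        return float(r @ r)

    j_map = objective(k_map)
    sds = posterior_sd_fim(k_map, data, prior, model)
    x_map = k_map.to_array()
    accepted = [k_map]
    n_tried = 0
    max_tries = max(config.n_confidence_samples * 200, 2000)
    positive = np.array(PARAMETER_NAMES) != "ku1"
    while len(accepted) < config.n_confidence_samples and n_tried < max_tries:
        x = x_map + proposal_scale * sds * rng.standard_normal(len(x_map))
        n_tried += 1
        if np.any(x[positive] < 0):
            continue
        k = ParameterSet.from_array(x)
        if objective(k) - j_map <= delta:
            accepted.append(k)
    if len(accepted) < config.n_confidence_samples:
        rate = len(accepted) / max(n_tried, 1)
        if rate < 1e-4:
            raise RuntimeError(
                f"confidence-set acceptance rate {rate:.2e}; rescale the proposal")
    return accepted[:config.n_confidence_samples]
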