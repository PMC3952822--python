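"""Core ODE model of ApoA-I and cholesteryl-ester kinetics in plasma.

Six species are tracked: lipid-poor ApoA-I, ApoA-I in the alpha-HDL pool,
the alpha-HDL particle concentration, and cholesteryl ester (CE) in HDL,
LDL and VLDL.  The processes are:

* ApoA-I synthesis into the lipid-poor pool and its kidney elimination;
* ABCA1-mediated lipidation of lipid-poor ApoA-I, generating nascent
  particles that carry ``gamma`` cholesterol molecules per ApoA-I — the
  initiation of reverse cholesterol transport (RCT);
* fusion of nascent particles with existing alpha-HDL (reducing the particle
  influx without affecting mass fluxes);
* dissociation of excess ApoA-I from alpha-HDL back to the lipid-poor pool,
  with the excess defined by the geometric surface model;
* size-dependent holo-particle uptake of alpha-HDL (removing particles,
  ApoA-I and CE together) and SRB1-mediated selective CE uptake;
* first-order CETP-mediated CE transfers HDL<->LDL and HDL->VLDL, VLDL->LDL
  conversion, CE synthesis into VLDL and CE elimination from LDL and VLDL.

All transfer and elimination steps are first order in their source pools;
syntheses are zero order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import ModelConstants
from . import geometry
from .geometry import ShenSurfaceConfig

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "StateVector",
    "DerivedOutputs",
    "ModelOptions",
    "RctModel",
    "SteadyStateError",
    "DEFAULT_INITIAL_STATE",
]

#: Canonical parameter ordering used by arrays, fixtures and the calibrator.
PARAMETER_NAMES = (
    "s_apoa1", "k_kidney", "k_diss", "k_abca1", "gamma",
    "k_hv", "k_hl", "k_lh", "k_vl", "s_vldl_ce",
    "k_ev", "k_el", "k_srb1", "ku0", "ku1", "k_fus",
)

#: Units of each parameter, for tabular output.
PARAMETER_UNITS = {
    "s_apoa1": "mg/dL/day", "k_kidney": "pool/day", "k_diss": "pool/day",
    "k_abca1": "pool/day", "gamma": "1", "k_hv": "pool/day",
    "k_hl": "pool/day", "k_lh": "pool/day", "k_vl": "pool/day",
    "s_vldl_ce": "mg/dL/day", "k_ev": "pool/day", "k_el": "pool/day",
    "k_srb1": "pool/day", "ku0": "pool/day", "ku1": "pool/day/nm",
    "k_fus": "1/(mmol/dL)",
}


@dataclass(frozen=True)
class ParameterSet:
    """The 16 kinetic and stoichiometric parameters of the model.

    Rate constants are in pool/day, syntheses in mg/dL/day; ``gamma`` is the
    FC-per-ApoA-I stoichiometry of nascent particles (dimensionless); ``ku0``
    and ``ku1`` are the size-independent (pool/day) and size-dependent
    (pool/day/nm) parts of the holo-uptake rate; ``k_fus`` (1/(mmol/dL))
    governs the particle-concentration dependence of nascent-particle fusion.
    ``ku1`` may be negative (uptake decreasing with size); all other
    parameters are non-negative.
    """

    s_apoa1: float
    k_kidney: float
    k_diss: float
    k_abca1: float
    gamma: float
    k_hv: float
    k_hl: float
    k_lh: float
    k_vl: float
    s_vldl_ce: float
    k_ev: float
    k_el: float
    k_srb1: float
    ku0: float
    ku1: float
    k_fus: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
            if name != "ku1" and v < 0:
                raise ValueError(f"parameter {name} must be non-negative, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAMETER_NAMES),):
            raise ValueError(f"expected {len(PARAMETER_NAMES)} parameters, "
                             f"got shape {values.shape}")
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    @classmethod
    def from_dict(cls, mapping) -> "ParameterSet":
        return cls(**{n: float(mapping[n]) for n in PARAMETER_NAMES})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAMETER_NAMES}

    def scaled(self, **factors) -> "ParameterSet":
        """Return a copy with named parameters multiplied by given factors."""
        updates = {k: getattr(self, k) * f for k, f in factors.items()}
        return replace(self, **updates)


STATE_NAMES = ("a_lp", "a_alpha", "p_hdl", "ce_hdl", "ce_ldl", "ce_vldl")


@dataclass(frozen=True)
class StateVector:
    """Plasma species: ApoA-I pools (mg/dL), particle concentration (mmol/dL),
    and CE pools (mg/dL, FC-equivalent mass)."""

    a_lp: float
    a_alpha: float
    p_hdl: float
    ce_hdl: float
    ce_ldl: float
    ce_vldl: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "StateVector":
        return cls(*[float(v) for v in np.asarray(values)])


#: Physiological default initial condition for steady-state searches.
DEFAULT_INITIAL_STATE = StateVector(5.0, 130.0, 1.5e-3, 35.0, 80.0, 5.0)


class DerivedOutputs(NamedTuple):
    """Observable lipoprotein measures computed from a state."""

    hdl_c: float            # mg/dL
    apoa1_total: float      # mg/dL
    hdl_p: float            # mmol/dL
    hdl_size: float         # nm
    frac_lipid_poor: float  # % of total ApoA-I (nan if total is 0)
    ldl_c: float            # mg/dL
    rct_rate: float         # mg/day, whole body
    fcr_apoa1: float        # pool/day
    hdl_ce_clearance: float  # L/day


@dataclass(frozen=True)
class ModelOptions:
    """Numerical and convention options.

    d_ref_nm : reference diameter (nm) in the holo-uptake law
        ``u = ku0 + ku1 (d/10 - d_ref_nm)``; the default is the nascent-sphere
        diameter, which keeps the uptake rate positive over the physiological
        size range with the nominal parameters.  Set to 0 for the unshifted
        form.
    u_min : floor of the holo-uptake rate (pool/day).
    clamp_excess : if True the remodeling flux is clamped at zero in deficit
        (no net re-association of lipid-poor ApoA-I).
    p_hdl_floor : particle concentration below which the pool is treated as
        degenerate (excess flux set to 0 and uptake to ku0 — the p -> 0 limit
        convention used for e.g. ABCA1-null simulations).
    rtol, atol : integration tolerances.
    t_final : horizon (days) of the steady-state relaxation integration.
    """

    d_ref_nm: float = 7.5
    u_min: float = 0.0
    clamp_excess: bool = False
    p_hdl_floor: float = 1e-12
    rtol: float = 1e-9
    atol: float = 1e-9
    t_final: float = 2000.0


class SteadyStateError(RuntimeError):
    """Steady-state search failed; carries the last iterate for diagnosis."""

    def __init__(self, message: str, state=None, residual=None):
        super().__init__(message)
        self.state = state
        self.residual = residual


class RctModel:
    """The ODE model bound to a set of constants, surface configuration and
    numerical options.

    The methods accept parameters as :class:`ParameterSet`; states as
    :class:`StateVector` or plain arrays in the canonical species order.
    The right-hand side is analytic in the state and supports complex input,
    which the tracer module exploits for complex-step sensitivities.
    """

    def __init__(self,
                 constants: ModelConstants = ModelConstants(),
                 surface: ShenSurfaceConfig = ShenSurfaceConfig(),
                 options: ModelOptions = ModelOptions()):
        self.constants = constants
        self.surface = surface
        self.options = options

    # -- elementary rate laws -------------------------------------------------

    def holo_uptake_rate(self, diameter, params: ParameterSet):
        """Size-dependent alpha-HDL holo-uptake rate (pool/day).

        ``diameter`` in A; the division by 10 converts to nm.
        """
        u = params.ku0 + params.ku1 * (diameter / 10.0 - self.options.d_ref_nm)
        if np.real(u) < self.options.u_min:
            return self.options.u_min + 0.0 * u
        return u

    def fusion_fraction(self, p_hdl, params: ParameterSet):
        """Probability that a nascent particle fuses with existing alpha-HDL.

        Nascent particles pass through two stages (disc, then sphere) before
        entering the pool as distinct particles; each stage is escaped with
        probability 1/(1 + k_fus * P), so the fused fraction is
        ``1 - (1 + k_fus P)^-2``.  Saturates to 1 as P grows; 0 at P = 0.
        """
        s = 1.0 + params.k_fus * p_hdl
        return 1.0 - 1.0 / (s * s)

    # -- right-hand side ------------------------------------------------------

    def rhs(self, state, params: ParameterSet):
        """Time derivative of the six species (per day)."""
        y = np.asarray(state.to_array() if isinstance(state, StateVector) else state)
        if not np.all(np.isfinite(np.real(y))):
            raise ValueError(f"non-finite state passed to rhs: {y}")
        a_lp, a_al, p, ce_h, ce_l, ce_v = y
        c = self.constants
        k = params

        if np.real(p) < self.options.p_hdl_floor:
            # degenerate pool: p -> 0 limit convention
            x_excess = 0.0 * a_al
            u = k.ku0
            n_fc = 0.0
        else:
            n_ce = geometry.ce_per_particle(ce_h, p, c)
            r = geometry.core_radius(n_ce, c)
            d = 2.0 * (r + c.shell_thickness)
            n_fc, _, _, n_shen, _ = geometry.shen_surface(r, self.surface, c)
            n_act = geometry.apoa1_per_particle(a_al, p, c)
            x_excess = (n_act - n_shen) * p * c.mw_apoa1
            if self.options.clamp_excess and np.real(x_excess) < 0:
                x_excess = 0.0 * x_excess
            u = self.holo_uptake_rate(d, k)

        phi = self.fusion_fraction(p, k)
        mass_ratio = c.mw_chol / c.mw_apoa1
        lipidation = k.k_abca1 * a_lp            # ApoA-I mass flux into alpha-HDL
        rct_input = k.gamma * mass_ratio * lipidation  # CE influx via nascent spheres

        d_a_lp = k.s_apoa1 - (k.k_abca1 + k.k_kidney) * a_lp + k.k_diss * x_excess
        d_a_al = lipidation - k.k_diss * x_excess - u * a_al
        d_p = ((1.0 - phi) * lipidation / (c.apoa1_per_nascent * c.mw_apoa1)
               - u * p)
        d_ce_h = (rct_input + k.k_lh * ce_l
                  - (k.k_hv + k.k_hl + k.k_srb1 + u) * ce_h)
        d_ce_l = k.k_vl * ce_v + k.k_hl * ce_h - (k.k_lh + k.k_el) * ce_l
        d_ce_v = k.s_vldl_ce + k.k_hv * ce_h - (k.k_vl + k.k_ev) * ce_v
        return np.array([d_a_lp, d_a_al, d_p, d_ce_h, d_ce_l, d_ce_v])

    # -- solving --------------------------------------------------------------

    def integrate(self, params: ParameterSet, t_span, y0=None, t_eval=None,
                  method: str = "LSODA", dense_output: bool = False):
        """Integrate the ODE system; thin wrapper over ``scipy.solve_ivp``."""
        if y0 is None:
            y0 = DEFAULT_INITIAL_STATE
        y0 = y0.to_array() if isinstance(y0, StateVector) else np.asarray(y0, float)
        sol = solve_ivp(lambda t, y: self.rhs(y, params), t_span, y0,
                        method=method, t_eval=t_eval,
                        rtol=self.options.rtol, atol=self.options.atol,
                        dense_output=dense_output)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}", y0)
        return sol

    def steady_state(self, params: ParameterSet, init: StateVector | None = None,
                     fast: bool = False) -> StateVector:
        """Equilibrium state of the system.

        A Newton-type root search is polished onto the fixed point; unless
        ``fast`` root-finding starts from the end of a long relaxation
        integration (default 2000 days) from a physiological initial state.
        With ``fast`` the root search starts directly from ``init`` (useful
        when a nearby steady state is known, e.g. across a virtual
        population), falling back to the integration path if it fails.
        Deterministic for a fixed ``init``.
        """
        y0 = (init or DEFAULT_INITIAL_STATE)
        y0 = y0.to_array() if isinstance(y0, StateVector) else np.asarray(y0, float)

        def try_polish(y):
            res = root(lambda z: self.rhs(z, params), y, method="hybr",
                       options={"xtol": 1e-13})
            if res.success and np.all(res.x > -1e-12):
                y_fix = np.maximum(res.x, 0.0)
                r = self.rhs(y_fix, params)
                scale = max(np.linalg.norm(y_fix), 1.0)
                if np.linalg.norm(r) / scale < 1e-10:
                    return y_fix
            return None

        if fast:
            y = try_polish(y0)
            if y is not None:
                return StateVector.from_array(y)

        sol = self.integrate(params, (0.0, self.options.t_final), y0)
        y_end = sol.y[:, -1]
        y = try_polish(y_end)
        if y is not None:
            return StateVector.from_array(y)
        # Degenerate parameter sets (e.g. ABCA1-null) equilibrate with an
        # empty particle pool where the Newton polish cannot improve; accept
        # the relaxed state if its residual is already tiny.
        r = self.rhs(y_end, params)
        if np.linalg.norm(r) / max(np.linalg.norm(y_end), 1.0) < 1e-8:
            return StateVector.from_array(np.maximum(y_end, 0.0))
        raise SteadyStateError(
            "steady-state search did not converge "
            f"(residual {np.linalg.norm(r):.3e} at state {y_end})",
            state=y_end, residual=r)

    # -- observables ----------------------------------------------------------

    def rct_rate(self, state: StateVector, params: ParameterSet) -> float:
        """Whole-body reverse cholesterol transport rate (mg/day).

        The FC flux loaded onto nascent discs: gamma FC per ApoA-I lipidated,
        converted to cholesterol mass and scaled by plasma volume (in dL).
        """
        c = self.constants
        per_dl = (params.gamma * (c.mw_chol / c.mw_apoa1)
                  * params.k_abca1 * state.a_lp)
        return per_dl * c.plasma_volume * 10.0

    def derived_outputs(self, state: StateVector, params: ParameterSet) -> DerivedOutputs:
        """Observable lipoprotein measures for a (typically steady) state."""
        c = self.constants
        total = state.a_lp + state.a_alpha
        if state.p_hdl >= self.options.p_hdl_floor:
            hdl_c = float(geometry.hdl_total_cholesterol(
                state.ce_hdl, state.p_hdl, self.surface, c))
            n_ce = geometry.ce_per_particle(state.ce_hdl, state.p_hdl, c)
            d = float(geometry.particle_diameter(n_ce, c))
            u = float(self.holo_uptake_rate(d, params))
        else:
            hdl_c = state.ce_hdl
            d = 2.0 * c.shell_thickness
            u = params.ku0
        frac = 100.0 * state.a_lp / total if total > 0 else float("nan")
        fcr = ((params.k_kidney * state.a_lp + u * state.a_alpha) / total
               if total > 0 else float("nan"))
        clearance = c.plasma_volume * (params.k_hv + params.k_hl
                                       + params.k_srb1 + u)
        return DerivedOutputs(
            hdl_c=hdl_c,
            apoa1_total=total,
            hdl_p=state.p_hdl,
            hdl_size=d / 10.0,
            frac_lipid_poor=frac,
            ldl_c=state.ce_ldl / c.ldl_ce_to_tc,
            rct_rate=self.rct_rate(state, params),
            fcr_apoa1=fcr,
            hdl_ce_clearance=clearance,
        )
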