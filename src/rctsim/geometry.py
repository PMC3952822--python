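"""Geometric submodel of spherical HDL particles.

An alpha-HDL particle is modelled as a hydrophobic core of cholesteryl ester
(CE) and triglyceride (TG) wrapped in a surface monolayer of fixed thickness
containing free cholesterol (FC), phospholipid (PL) and protein.  From the CE
content per particle the core radius follows, and from the core radius the
surface composition — in particular the number of ApoA-I molecules required
to cover the particle.  The mismatch between the ApoA-I actually present and
this surface requirement is the "excess" ApoA-I available to dissociate back
to the lipid-poor pool (the remodeling flux), the mechanism that couples
ApoA-I turnover to particle size in the model.

Surface bookkeeping: FC is assigned a fixed fraction of the core surface
area; PL covers the remainder of the core surface; protein covers the annular
area by which the outer surface exceeds the core surface.  The cross-sectional
areas and the FC coverage fraction are exposed in :class:`ShenSurfaceConfig`.
The defaults are provisional transcriptions chosen to reproduce published HDL
surface composition (FC/PL molar ratio ~0.2, 2-4 ApoA-I per particle over the
physiological 7.5-13 nm size range); treat them as configuration, not as
measured constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .constants import ModelConstants

__all__ = [
    "ShenSurfaceConfig",
    "ParticleGeometry",
    "ce_per_particle",
    "core_radius",
    "particle_diameter",
    "apoa1_per_particle",
    "shen_surface",
    "particle_geometry",
    "excess_apoa1_conc",
    "hdl_total_cholesterol",
]

_FOUR_PI = 4.0 * math.pi


@dataclass(frozen=True)
class ShenSurfaceConfig:
    """Surface-coverage constants of the geometric submodel.

    area_fc, area_pl, area_aa : cross-sectional areas (A^2) of a free
        cholesterol molecule, a phospholipid, and an amino-acid residue.
    fc_core_fraction : fraction of the core surface area occupied by FC;
        this is the rule generating n_FC from the core radius.
    """

    area_fc: float = 38.0
    area_pl: float = 62.0
    area_aa: float = 14.0
    fc_core_fraction: float = 0.13

    def __post_init__(self) -> None:
        if min(self.area_fc, self.area_pl, self.area_aa) <= 0:
            raise ValueError("all cross-sectional areas must be positive")


class ParticleGeometry(NamedTuple):
    """Per-particle composition and size of a spherical alpha-HDL particle."""

    n_ce: float
    core_volume: float
    core_radius: float
    diameter: float
    n_fc: float
    n_pl: float
    n_aa: float
    n_apoa1_shen: float
    n_apoa1_actual: float
    clamped: bool


def ce_per_particle(ce_hdl, p_hdl, constants: ModelConstants = ModelConstants()):
    """CE molecules per HDL particle from pool concentrations.

    ce_hdl in mg/dL (FC-equivalent mass), p_hdl in mmol/dL.  Division by the
    cholesterol molecular weight (mg/mmol) converts mass to molar
    concentration, division by the particle concentration gives the count.
    """
    if np.any(np.real(p_hdl) <= 0):
        raise ValueError("particle concentration must be positive; degenerate "
                         "pools are guarded at the model level")
    return (ce_hdl / constants.mw_chol) / p_hdl


def core_radius(n_ce, constants: ModelConstants = ModelConstants()):
    """Core radius (A) of a particle carrying ``n_ce`` CE molecules.

    The core volume sums CE and the implicit TG at the assumed TG/CE ratio.
    Accepts complex input (analytic in n_ce) for complex-step sensitivities.
    """
    vol = n_ce * (constants.vol_ce + constants.tg_to_ce_ratio * constants.vol_tg)
    return (3.0 * vol / _FOUR_PI) ** (1.0 / 3.0)


def particle_diameter(n_ce, constants: ModelConstants = ModelConstants()):
    """Particle diameter (A): twice core radius plus surface thickness."""
    return 2.0 * (core_radius(n_ce, constants) + constants.shell_thickness)


def apoa1_per_particle(a_alpha, p_hdl, constants: ModelConstants = ModelConstants()):
    """ApoA-I molecules per particle from the alpha-pool ApoA-I concentration."""
    if np.any(np.real(p_hdl) <= 0):
        raise ValueError("particle concentration must be positive; degenerate "
                         "pools are guarded at the model level")
    return (a_alpha / constants.mw_apoa1) / p_hdl


def shen_surface(radius, cfg: ShenSurfaceConfig = ShenSurfaceConfig(),
                 constants: ModelConstants = ModelConstants()):
    """Surface composition from the core radius.

    Returns ``(n_fc, n_pl, n_aa, n_apoa1_shen, clamped)``.  ``n_fc`` follows
    the configured FC coverage fraction of the core surface; ``n_pl`` covers
    the remaining core surface; ``n_aa`` covers the hydrophobic area exposed
    at the outer surface layer; ``n_apoa1_shen`` converts amino acids to
    ApoA-I molecules through the proteome weight fraction and the ApoA-I
    residue count.  If FC coverage would exceed the core surface, PL is
    clamped at zero and the flag is set.
    """
    t = constants.shell_thickness
    a_core = _FOUR_PI * radius * radius
    a_outer = _FOUR_PI * (radius + t) * (radius + t)
    n_fc = cfg.fc_core_fraction * a_core / cfg.area_fc
    remaining = a_core - n_fc * cfg.area_fc
    clamped = bool(np.real(remaining) < 0)
    if clamped:
        remaining = 0.0 * remaining
    n_pl = remaining / cfg.area_pl
    n_aa = (a_outer - n_pl * cfg.area_pl - n_fc * cfg.area_fc) / cfg.area_aa
    n_apoa1 = constants.apoa1_weight_fraction * n_aa / constants.apoa1_residues
    return n_fc, n_pl, n_aa, n_apoa1, clamped


def particle_geometry(ce_hdl, a_alpha, p_hdl,
                      cfg: ShenSurfaceConfig = ShenSurfaceConfig(),
                      constants: ModelConstants = ModelConstants()) -> ParticleGeometry:
    """Full geometric description of the mean alpha-HDL particle."""
    n_ce = ce_per_particle(ce_hdl, p_hdl, constants)
    r = core_radius(n_ce, constants)
    vol = n_ce * (constants.vol_ce + constants.tg_to_ce_ratio * constants.vol_tg)
    d = 2.0 * (r + constants.shell_thickness)
    n_fc, n_pl, n_aa, n_shen, clamped = shen_surface(r, cfg, constants)
    n_act = apoa1_per_particle(a_alpha, p_hdl, constants)
    return ParticleGeometry(n_ce, vol, r, d, n_fc, n_pl, n_aa, n_shen, n_act, clamped)


def excess_apoa1_conc(a_alpha, ce_hdl, p_hdl,
                      cfg: ShenSurfaceConfig = ShenSurfaceConfig(),
                      constants: ModelConstants = ModelConstants()):
    """Concentration (mg/dL) of excess ApoA-I on the alpha-HDL pool.

    Signed: positive when particles carry more ApoA-I than their surface
    requires (available to dissociate), negative when in deficit (driving net
    association of lipid-poor ApoA-I).
    """
    geo_r = core_radius(ce_per_particle(ce_hdl, p_hdl, constants), constants)
    *_, n_shen, _ = shen_surface(geo_r, cfg, constants)
    n_act = apoa1_per_particle(a_alpha, p_hdl, constants)
    return (n_act - n_shen) * p_hdl * constants.mw_apoa1


def hdl_total_cholesterol(ce_hdl, p_hdl,
                          cfg: ShenSurfaceConfig = ShenSurfaceConfig(),
                          constants: ModelConstants = ModelConstants()):
    """HDL-C (mg/dL): the CE pool plus the implicit surface FC pool."""
    if np.all(np.real(p_hdl) == 0):
        return ce_hdl
    r = core_radius(ce_per_particle(ce_hdl, p_hdl, constants), constants)
    n_fc, *_ = shen_surface(r, cfg, constants)
    return ce_hdl + n_fc * p_hdl * constants.mw_chol
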