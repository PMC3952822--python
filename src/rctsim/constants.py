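"""Physical constants of the lipoprotein model and study-arm pooling arithmetic.

The model works in the conventional clinical units: concentrations of ApoA-I
and cholesterol species in mg/dL, HDL particle concentration in mmol/dL, rate
constants in pool/day.  Cholesteryl ester (CE) mass is always expressed as the
equivalent mass of free cholesterol (FC), so a single cholesterol molecular
weight serves both species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ModelConstants",
    "StudyArm",
    "pool_means",
    "pool_sems",
    "inflate_uncertainty",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physical and compositional constants of the model.

    Attributes
    ----------
    mw_apoa1 : float
        Molecular weight of ApoA-I (g/mol).
    mw_chol : float
        Molecular weight of cholesterol, free or esterified measured as
        free-cholesterol equivalents (g/mol).
    vol_ce, vol_tg : float
        Molecular volumes of cholesteryl ester and triglyceride (A^3).
    shell_thickness : float
        Thickness of the lipoprotein surface monolayer (A).
    tg_to_ce_ratio : float
        Assumed TG/CE molar-volume ratio in the core of alpha-HDL.
    apoa1_weight_fraction : float
        Weight fraction of ApoA-I in the HDL proteome.
    apoa1_residues : int
        Number of amino-acid residues in ApoA-I.
    apoa1_per_nascent : int
        ApoA-I molecules per nascent HDL particle.
    plasma_volume : float
        Plasma volume of the reference 70 kg adult (L).
    ldl_ce_to_tc : float
        Ratio used to convert LDL total cholesterol to LDL-CE.
    """

    mw_apoa1: float = 28500.0
    mw_chol: float = 386.0
    vol_ce: float = 1068.0
    vol_tg: float = 1556.0
    shell_thickness: float = 20.2
    tg_to_ce_ratio: float = 0.13
    apoa1_weight_fraction: float = 0.60
    apoa1_residues: int = 243
    apoa1_per_nascent: int = 2
    plasma_volume: float = 3.15
    ldl_ce_to_tc: float = 0.7


@dataclass(frozen=True)
class StudyArm:
    """One study arm contributing to a pooled observable: n subjects, mean, SD."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"study arm must have n >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"study arm SD must be >= 0, got {self.sd}")


def _as_arms(arms: Iterable) -> list[StudyArm]:
    out = [a if isinstance(a, StudyArm) else StudyArm(*a) for a in arms]
    if not out:
        raise ValueError("cannot pool an empty list of study arms")
    return out


def pool_means(arms: Sequence[StudyArm | tuple]) -> float:
    """n-weighted mean of study-arm means.

    Arms may be given as ``StudyArm`` objects or ``(n, mean[, sd])`` tuples.
    Returns the unrounded pooled mean; round to the printed precision of the
    source table when reproducing fixture values.
    """
    arms = _as_arms(arms)
    n_tot = sum(a.n for a in arms)
    return sum(a.n * a.mean for a in arms) / n_tot


def pool_sems(arms: Sequence[StudyArm | tuple]) -> float:
    """Pooled standard error of the mean across study arms.

    The pooled variance is the n-weighted second moment about the pooled
    mean, i.e. it includes both the within-arm variances and the between-arm
    dispersion:

        var = sum_i n_i (sd_i^2 + (m_i - m)^2) / N,   SEM = sqrt(var / N)

    which is the SEM that would be obtained from the concatenated individual
    data if each arm were internally normal with the stated moments.
    """
    arms = _as_arms(arms)
    n_tot = sum(a.n for a in arms)
    m = pool_means(arms)
    var = sum(a.n * (a.sd**2 + (a.mean - m) ** 2) for a in arms) / n_tot
    return math.sqrt(var / n_tot)


def inflate_uncertainty(sem: float) -> float:
    """Inflate an uncertainty by sqrt(2).

    Applied to prior uncertainties that were obtained by mapping in-vitro or
    mutation-carrier measurements to the normal in-vivo context, or by pooling
    across distinct experimental techniques.
    """
    if sem < 0:
        raise ValueError(f"uncertainty must be non-negative, got {sem}")
    return sem * math.sqrt(2.0)
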