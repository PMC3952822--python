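"""Versioned in-package data: parameter priors/posteriors and calibration
tables, shipped as plain CSV (each file carries a ``unit`` column) and loaded
read-only through :func:`load_fixtures`.

The pooled HDL-C/ApoA-I values for normal subjects and CETP-deficiency
carriers are shipped both as raw study arms (for the pooling arithmetic) and
as the canonical pooled cells used in calibration residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .model import PARAMETER_NAMES, ParameterSet

__all__ = [
    "PriorSpec",
    "FcrRelation",
    "CalibrationDataset",
    "load_fixtures",
    "default_fcr_relation",
]

#: Scenario tags of the calibration data: nominal subject, CETP-deficiency
#: heterozygote (50% CETP activity) and homozygote (0%).
SCENARIOS = ("normal", "cetp_het", "cetp_hom")

#: CETP activity factor per scenario.
SCENARIO_CETP_SCALE = {"normal": 1.0, "cetp_het": 0.5, "cetp_hom": 0.0}


def _read(name: str) -> pd.DataFrame:
    with resources.files("rctsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors for the 16 parameters, in canonical order.

    ``informative`` is False exactly for the two parameters estimated without
    prior information (the size-dependent uptake slope and the fusion
    parameter); those contribute zero precision to the posterior objective.
    """

    means: np.ndarray
    sds: np.ndarray
    informative: np.ndarray

    def __post_init__(self):
        if np.any(self.sds[self.informative] <= 0):
            raise ValueError("informative prior SDs must be positive")

    @property
    def n_informative(self) -> int:
        return int(np.sum(self.informative))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": PARAMETER_NAMES, "mean": self.means,
                             "sd": self.sds, "informative": self.informative})


@dataclass(frozen=True)
class FcrRelation:
    """Piecewise-linear target relation between ApoA-I FCR (pool/day) and the
    HDL-C/ApoA-I ratio (a surrogate of HDL size), with a floor.

    ``sd_band`` is the 1-SD half-width of the relation used to weight FCR
    residuals in calibration.
    """

    slope: float
    intercept: float
    floor: float = 0.135
    sd_band: float = 0.065

    def __call__(self, ratio: float) -> float:
        return max(self.floor, self.intercept + self.slope * ratio)


def default_fcr_relation() -> FcrRelation:
    """Default FCR-vs-size line, anchored at two observed points: an FCR of
    1/4.8 pool/day (the measured ApoA-I residence time of 4.8 days) at the
    pooled normal HDL-C/ApoA-I ratio, and the floor of 0.135 pool/day at the
    pooled CETP-homozygote ratio (carriers of the largest particles)."""
    ratio_normal = 52.0 / 139.0
    ratio_hom = 166.0 / 232.0
    fcr_normal = 1.0 / 4.8
    floor = 0.135
    slope = (floor - fcr_normal) / (ratio_hom - ratio_normal)
    intercept = fcr_normal - slope * ratio_normal
    return FcrRelation(slope=slope, intercept=intercept, floor=floor,
                       sd_band=0.065)


@dataclass(frozen=True)
class CalibrationDataset:
    """Pooled observables with uncertainties, plus the FCR target relation.

    ``observables`` rows are (scenario, quantity, value, sem): six HDL
    measures (HDL-C and total ApoA-I per scenario) and three ApoB-particle CE
    pools.  ``ce_fluxes`` rows are (flux name, value, sem) in mg/dL/day.
    Together with the three scenario FCR targets drawn from ``fcr_relation``
    this yields 15 data residuals.
    """

    observables: tuple
    ce_fluxes: tuple
    fcr_relation: FcrRelation = field(default_factory=default_fcr_relation)

    @property
    def n_residuals(self) -> int:
        return len(self.observables) + len(self.ce_fluxes) + len(SCENARIOS)


def _load_prior() -> PriorSpec:
    df = _read("parameters.csv").set_index("parameter").loc[list(PARAMETER_NAMES)]
    return PriorSpec(means=df["prior_mean"].to_numpy(float),
                     sds=df["prior_sd"].to_numpy(float),
                     informative=df["informative"].to_numpy(bool))


def _load_posterior() -> ParameterSet:
    df = _read("parameters.csv").set_index("parameter")
    return ParameterSet.from_dict(df["posterior_mean"].to_dict())


def _load_posterior_sd() -> np.ndarray:
    df = _read("parameters.csv").set_index("parameter").loc[list(PARAMETER_NAMES)]
    return df["posterior_sd"].to_numpy(float)


def _load_calibration() -> CalibrationDataset:
    pooled = _read("hdl_calibration_pooled.csv")
    apob = _read("apob_ce.csv")
    obs = [
        (row["scenario"], row["quantity"], float(row["mean"]), float(row["sem"]))
        for _, row in pd.concat([pooled, apob], ignore_index=True).iterrows()
    ]
    fluxes = [
        (row["flux"], float(row["mean"]), float(row["sem"]))
        for _, row in _read("ce_fluxes.csv").iterrows()
    ]
    return CalibrationDataset(observables=tuple(obs), ce_fluxes=tuple(fluxes))


_LOADERS = {
    "constants": lambda: ModelConstants(),
    "prior": _load_prior,
    "posterior_nominal": _load_posterior,
    "posterior_sd": _load_posterior_sd,
    "calibration": _load_calibration,
    "calibration_arms": lambda: _read("hdl_calibration_arms.csv"),
}


def load_fixtures(name: str):
    """Load a named fixture.

    Known names: ``constants`` (ModelConstants), ``prior`` (PriorSpec),
    ``posterior_nominal`` (ParameterSet of nominal-subject estimates),
    ``posterior_sd`` (their SDs, canonical order), ``calibration``
    (CalibrationDataset), ``calibration_arms`` (raw study-arm DataFrame).
    """
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_LOADERS)}")
    return loader()
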