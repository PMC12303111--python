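"""Tag-retention modelling: removal forces, detachment risk and trial fits.

A bur-attached tag stays on as long as the forces the animal generates
stay below the adhesive's measured removal force.  This module provides
the dynamic-force rule (F = ma with peak accelerations of 1–7 g), a risk
assessment against measured removal forces, OLS fitting of removal-force
trials (bur count, driver mass, pull direction, substrate), and grouped
summaries in the mean (s.d., n) reporting format of pull-off experiments.

Forces are in millinewtons and masses in grams, the natural units of
spring-balance pull-off trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import linalg

from .gate_ballistics import G0

__all__ = [
    "PULL_DIRECTIONS",
    "TRIAL_COLUMNS",
    "RetentionModel",
    "RiskReport",
    "SingularDesignError",
    "dynamic_removal_force",
    "detachment_risk",
    "fit_retention_model",
    "adhesion_summary",
    "validate_trials",
]

PULL_DIRECTIONS = ("against_fur", "perpendicular_across", "perpendicular_away", "with_fur")

#: required columns of a removal-force trials table
TRIAL_COLUMNS = ("substrate", "bur_count", "driver_mass_g", "pull_direction", "removal_force_mN")


class SingularDesignError(ValueError):
    """Raised when the trial design matrix is rank-deficient."""


@dataclass(frozen=True)
class RiskReport:
    """Outcome of a detachment-risk assessment."""

    dynamic_force_mN: float
    measured_removal_force_mN: float
    force_ratio: float
    at_risk: bool


@dataclass
class RetentionModel:
    """Fitted linear model of removal force.

    Coefficients are treatment-coded: categorical effects are offsets in
    mN relative to the alphabetically first level of each covariate.
    """

    intercept: float
    bur_effect: float
    mass_slope: float
    direction_effects: dict = field(default_factory=dict)
    substrate_effects: dict = field(default_factory=dict)
    variance_explained: float = 0.0
    std_errors: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)
    n: int = 0
    reference_levels: dict = field(default_factory=dict)


def dynamic_removal_force(tag_mass: float, acceleration: float) -> float:
    """Force a moving animal exerts on its tag, F = m·a (Newton's second law).

    Parameters are the tag mass in grams and the animal's peak dynamic
    acceleration in multiples of g; the result is in mN.  A 10 g tag at
    7 g generates ≈687 mN, a 20 g tag twice that.
    """
    if tag_mass <= 0:
        raise ValueError("tag_mass must be > 0")
    if acceleration <= 0:
        raise ValueError("acceleration must be > 0")
    # g → kg gives 1e-3, N → mN gives 1e3: they cancel
    return tag_mass * acceleration * G0


def detachment_risk(
    measured_removal_force: float,
    tag_mass: float,
    acceleration_range: tuple[float, float] = (1.0, 7.0),
) -> RiskReport:
    """Assess whether typical movement could dislodge an attached tag.

    The tag is flagged at risk when the dynamic force at the top of the
    acceleration range exceeds the measured removal force of the adhesive
    on that fur.
    """
    if measured_removal_force <= 0:
        raise ValueError("measured_removal_force must be > 0")
    lo, hi = acceleration_range
    if not (0 < lo <= hi):
        raise ValueError("acceleration_range must satisfy 0 < low <= high")
    dynamic = dynamic_removal_force(tag_mass, hi)
    ratio = dynamic / measured_removal_force
    return RiskReport(
        dynamic_force_mN=dynamic,
        measured_removal_force_mN=float(measured_removal_force),
        force_ratio=ratio,
        at_risk=bool(ratio > 1.0),
    )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a removal-force trials table against the expected schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table is missing columns: {missing}")
    if (trials["removal_force_mN"] < 0).any():
        raise ValueError("removal_force_mN must be >= 0")
    if (trials["driver_mass_g"] <= 0).any():
        raise ValueError("driver_mass_g must be > 0")
    if (trials["bur_count"] < 1).any():
        raise ValueError("bur_count must be >= 1")
    bad = set(trials["pull_direction"]) - set(PULL_DIRECTIONS)
    if bad:
        raise ValueError(f"unknown pull_direction levels: {sorted(bad)}")
    return trials


def _check_rank(result) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the columns beyond the numerical rank via pivoted QR
        _, _, piv = linalg.qr(exog, mode="economic", pivoting=True)
        names = np.asarray(result.model.exog_names)
        collinear = sorted(names[piv[rank:]])
        raise SingularDesignError(
            f"design matrix is rank-deficient; collinear columns: {collinear}"
        )


def fit_retention_model(trials: pd.DataFrame, *, interactions: bool = False) -> RetentionModel:
    """Fit removal force ~ driver mass + bur count + substrate + direction by OLS.

    Categorical covariates use treatment contrasts with the alphabetically
    first level as reference (recorded in ``reference_levels``).  Covariates
    need at least two observed levels and n must exceed the number of
    coefficients.  ``interactions=True`` adds the pairwise
    driver-mass × bur-count and substrate × direction terms.
    """
    trials = validate_trials(pd.DataFrame(trials))
    for col in ("substrate", "pull_direction", "bur_count"):
        if trials[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} needs >= 2 observed levels to be fitted")

    formula = "removal_force_mN ~ driver_mass_g + bur_count + C(substrate) + C(pull_direction)"
    if interactions:
        formula += " + driver_mass_g:bur_count + C(substrate):C(pull_direction)"
    result = smf.ols(formula, data=trials).fit()
    if result.df_resid <= 0:
        raise ValueError("need more trials than fitted coefficients")
    _check_rank(result)

    ci = result.conf_int()

    def _cat_effects(prefix: str) -> dict:
        return {
            name.split("[T.")[1].rstrip("]"): float(result.params[name])
            for name in result.params.index
            if name.startswith(prefix) and "[T." in name and ":" not in name
        }

    return RetentionModel(
        intercept=float(result.params["Intercept"]),
        bur_effect=float(result.params["bur_count"]),
        mass_slope=float(result.params["driver_mass_g"]),
        direction_effects=_cat_effects("C(pull_direction)"),
        substrate_effects=_cat_effects("C(substrate)"),
        variance_explained=float(result.rsquared),
        std_errors={k: float(v) for k, v in result.bse.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
        n=int(result.nobs),
        reference_levels={
            "substrate": sorted(trials["substrate"].unique())[0],
            "pull_direction": sorted(trials["pull_direction"].unique())[0],
        },
    )


def adhesion_summary(trials: pd.DataFrame, grouping: list[str]) -> pd.DataFrame:
    """Group mean, sample s.d. (n−1 denominator) and n of removal forces.

    Mirrors the "x mN (s.d. y)" reporting of pull-off experiments; s.d. is
    missing (NaN) for single-trial groups.  Groups are ordered by the
    grouping keys.
    """
    trials = pd.DataFrame(trials)
    if trials.empty:
        raise ValueError("trials table is empty")
    unknown = [g for g in grouping if g not in trials.columns]
    if unknown:
        raise ValueError(f"unknown grouping keys: {unknown}")
    out = (
        trials.groupby(list(grouping), sort=True)["removal_force_mN"]
        .agg(mean_mN="mean", sd_mN=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return out
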