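"""Outcome model and bias diagnostics.

Within each (sub)sample, posttest is regressed by OLS on an intercept, a
0/1 treatment indicator, age, and pretest — the ANCOVA-style model used
throughout school-based intervention trials.  The treatment coefficient is
the intervention effect estimate; because all variables are z-scores it is
already a standardized effect size.  Percent bias compares a subsample's
estimate with the same replication's full-sample estimate, which serves as
the "true" effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import SimulationConfig
from .population import TREATMENT

FULL_SAMPLE = "full"

PREDICTORS = ("condition", "age", "pretest")


class SingularDesignError(ValueError):
    """Raised when a design column is constant over the selected rows."""


@dataclass(frozen=True)
class ModelFit:
    """OLS results for one sample definition within one replication."""

    sample_name: str
    n: int
    effect_estimate: float
    effect_se: float
    r_squared: float
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        # zero only in exactly collinear (noise-free) toy data
        if self.effect_se < 0:
            raise ValueError("effect_se must be non-negative")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("n must exceed the number of parameters")


def fit_outcome_model(
    table: pd.DataFrame, eligibility_flag: str = "all", sample_name: str | None = None
) -> ModelFit:
    """Fit posttest ~ condition + age + pretest over the flagged rows.

    ``eligibility_flag`` names a boolean column (e.g. ``eligible_method_1``)
    or ``"all"`` for the full screening sample.  Standard errors are the
    conventional homoskedastic OLS ones and ``r_squared`` the ordinary
    coefficient of determination.
    """
    if eligibility_flag == "all":
        rows = table
        name = sample_name or FULL_SAMPLE
    else:
        if eligibility_flag not in table.columns:
            raise KeyError(f"no eligibility column {eligibility_flag!r}")
        rows = table[table[eligibility_flag]]
        name = sample_name or eligibility_flag.removeprefix("eligible_")
    if len(rows) < 5:
        raise ValueError(f"sample {name!r} has fewer than 5 rows")

    design = pd.DataFrame(
        {
            "condition": (rows["condition"] == TREATMENT).astype(float),
            "age": rows["age"].to_numpy(),
            "pretest": rows["pretest"].to_numpy(),
        }
    )
    for col in PREDICTORS:
        if design[col].nunique() < 2:
            raise SingularDesignError(
                f"predictor {col!r} is constant over sample {name!r}"
            )
    res = sm.OLS(rows["posttest"].to_numpy(), sm.add_constant(design)).fit()
    coefs = {"intercept": res.params["const"]}
    coefs.update({c: res.params[c] for c in PREDICTORS})
    return ModelFit(
        sample_name=name,
        n=len(rows),
        effect_estimate=float(res.params["condition"]),
        effect_se=float(res.bse["condition"]),
        r_squared=float(res.rsquared),
        coefficients=coefs,
    )


def percent_bias(
    estimate: float, reference: float, convention: str = "overestimate_positive"
) -> float:
    """Signed percent deviation of an estimate from its reference.

    The default convention returns ``100 * (estimate - reference) /
    reference`` so that overestimation is positive.  The alternative
    ``"reference_minus_estimate"`` convention flips the sign (some table
    footnotes define bias as (true − observed)/true); magnitudes and
    dispersions are identical either way.
    """
    if reference == 0:
        raise ValueError("percent bias undefined for a zero reference effect")
    pb = 100.0 * (estimate - reference) / reference
    if convention == "overestimate_positive":
        return pb
    if convention == "reference_minus_estimate":
        return -pb
    raise ValueError(f"unknown percent-bias convention {convention!r}")


def true_effect_reference(fits: Mapping[str, ModelFit]) -> float:
    """The replication's reference ("true") effect: the full-sample estimate.

    The reference is deliberately the full screening sample's estimate from
    the *same* replication, not the fixed generative mean — subsample bias
    is then attributable to selection alone, not to sampling error shared
    with the full sample.
    """
    if FULL_SAMPLE not in fits:
        raise KeyError("no full-sample fit present")
    return fits[FULL_SAMPLE].effect_estimate


def u_ratio(selected_sd: float, full_sd: float) -> float:
    """Restriction ratio: SD in the selected sample over SD in the full one.

    Values below 1 quantify how strongly selection truncated the variable;
    the reciprocal convention is obtained by swapping the arguments.
    """
    if selected_sd <= 0 or full_sd <= 0:
        raise ValueError("u-ratio requires strictly positive SDs")
    return selected_sd / full_sd


@dataclass(frozen=True)
class AnalyticMoments:
    """Closed-form full-sample expectations under the generative model."""

    residual_variance: float
    total_variance: float
    effect_se: float
    r_squared: float


def expected_full_sample_moments(config: SimulationConfig) -> AnalyticMoments:
    """Analytic full-sample residual variance, effect SE and R².

    Under the generative model the conditional variance of the
    pre-injection posttest given (age, pretest) is ``1 − b' Σxx⁻¹ b`` with
    ``b`` the posttest–covariate correlations.  Heterogeneous effect draws
    add ``effect_sd²/2`` to the pooled residual (half the sample is
    treated).  With a balanced 0/1 indicator orthogonal to the covariates,
    ``SE = sqrt(4·residual/n)``; total posttest variance adds the
    between-condition component ``effect_mean²/4``.
    """
    b = np.array([config.r_age_post, config.r_pre_post])
    sxx = np.array([[1.0, config.r_age_pre], [config.r_age_pre, 1.0]])
    conditional = 1.0 - b @ np.linalg.solve(sxx, b)
    residual = conditional + config.effect_sd**2 / 2.0
    total = 1.0 + config.effect_sd**2 / 2.0 + config.effect_mean**2 / 4.0
    se = float(np.sqrt(residual / (config.n_students / 4.0)))
    return AnalyticMoments(
        residual_variance=float(residual),
        total_variance=float(total),
        effect_se=se,
        r_squared=float(1.0 - residual / total),
    )
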