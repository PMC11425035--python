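"""Regression models for active-travel prevalence, participation and intensity.

Three multivariate models parameterize the HOT health model for each
population subgroup:

* ``prevalence`` — logistic regression on the indicator of nonzero
  travel activity on the one survey day (I[TA > 0]);
* ``participation`` — logistic regression on the indicator of at least
  one self-reported walk or cycle trip over the past week
  (I[nwalk + ncycle > 0]);
* ``log_intensity`` — linear regression of log daily travel activity
  (log MET-hours/day) among active travelers only.

Covariates are the survey's social and environmental variables (sex,
age, race, Hispanic status, household income, education, census-block
population density, cars per household) plus state and a state-by-season
interaction as surrogates for infrastructure, climate and the state-level
oversampling of the survey design.  Fits are unweighted by default: the
state terms absorb the oversampling, and a ``weighted`` switch is
available for sensitivity analysis.

Subgroup parameters are extracted by predicting at a fixed reference
covariate profile with one (or more) variables overridden; probabilities
come from the inverse-logit of the logistic linear predictor.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

#: Reference covariate profile: White, non-Hispanic, male residents of
#: California with household income USD 35,000-49,999, a high-school
#: education, census-block density 2,000-3,999 per sq. mi., two household
#: cars, surveyed in the fall.
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "sex": "male",
    "race": "white",
    "hispanic": "no",
    "income_bracket": "35-50k",
    "education": "highschool",
    "pop_density_bin": "2000-3999",
    "n_cars": "2",
    "state": "CA",
    "season": "fall",
}

#: Model terms; "a:b" denotes an interaction.
DEFAULT_TERMS: tuple[str, ...] = (
    "sex",
    "age",
    "pop_density_bin",
    "income_bracket",
    "education",
    "n_cars",
    "race",
    "hispanic",
    "race:hispanic",
    "state",
    "state:season",
)

RESPONSES = ("prevalence", "participation", "log_intensity")


class ModelError(RuntimeError):
    """Raised when a regression cannot be fit (separation, collinearity)."""


@dataclass
class ModelSpec:
    """Specification of one regression model.

    Parameters
    ----------
    response
        One of ``prevalence``, ``participation``, ``log_intensity``.
    terms
        Ordered covariate names; ``"a:b"`` adds an interaction.
    reference_levels
        Reference level for every categorical term.
    """

    response: str
    terms: tuple[str, ...] = DEFAULT_TERMS
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        self.terms = tuple(self.terms)
        for term in self.terms:
            for var in term.split(":"):
                if var != "age" and var not in self.reference_levels:
                    raise ValueError(
                        f"no reference level for categorical term {var!r}"
                    )

    @property
    def family(self) -> str:
        return "linear" if self.response == "log_intensity" else "logistic"

    def categorical_variables(self) -> list[str]:
        seen: list[str] = []
        for term in self.terms:
            for var in term.split(":"):
                if var != "age" and var not in seen:
                    seen.append(var)
        return seen

    def formula(self, lhs: str = "_y") -> str:
        if not self.terms:
            return f"{lhs} ~ 1"
        parts = []
        for term in self.terms:
            factors = []
            for var in term.split(":"):
                if var == "age":
                    factors.append("age")
                else:
                    ref = self.reference_levels[var]
                    factors.append(f"C({var}, Treatment({ref!r}))")
            parts.append(":".join(factors))
        return f"{lhs} ~ " + " + ".join(parts)


@dataclass
class GlmFit:
    """A fitted regression: coefficients keyed by term.

    ``coefficients`` uses plain term names — ``intercept``, ``age``,
    ``var:level`` and ``var:level&var2:level2`` for interactions.
    ``residual_sd`` is the degrees-of-freedom-corrected root mean square
    residual (sigma0 of the intensity model); present only for the
    linear family.
    """

    coefficients: dict[str, float]
    family: str
    n_used: int
    residual_sd: float | None = None
    spec: ModelSpec | None = None
    age_mean: float | None = None
    standard_errors: dict[str, float] = field(default_factory=dict)
    _result: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if "intercept" not in self.coefficients:
            raise ValueError("fit has no intercept")
        if (self.residual_sd is not None) != (self.family == "linear"):
            raise ValueError("residual_sd present iff family is linear")

    def predict_linear(self, profile: dict[str, object]) -> float:
        """Linear predictor at a covariate profile (log-odds or log-intensity)."""
        if self._result is None or self.spec is None:
            raise ModelError("fit carries no design information for prediction")
        row = {v: self.spec.reference_levels[v] for v in self.spec.categorical_variables()}
        row["age"] = self.age_mean if self.age_mean is not None else 0.0
        row.update(profile)
        exog = pd.DataFrame([row])
        if self.family == "logistic":
            pred = self._result.predict(exog, which="linear")
        else:
            pred = self._result.predict(exog)
        return float(np.asarray(pred)[0])

    def to_json(self, path: str) -> None:
        payload = {
            "family": self.family,
            "n_used": self.n_used,
            "residual_sd": self.residual_sd,
            "age_mean": self.age_mean,
            "coefficients": self.coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class SubgroupSpec:
    """A subgroup: the reference profile with some variables overridden."""

    overrides: tuple[tuple[str, str], ...] = ()
    name: str = ""

    @classmethod
    def reference(cls) -> "SubgroupSpec":
        return cls((), "reference")

    @classmethod
    def single(cls, variable: str, level: str, name: str | None = None) -> "SubgroupSpec":
        return cls(((variable, level),), name or f"{variable}={level}")

    def as_dict(self) -> dict[str, str]:
        return dict(self.overrides)


@dataclass
class SubgroupParams:
    """HOT parameters for one subgroup.

    participation_pi (pi_j) is the weekly participation probability,
    prevalence_p (p_j) the one-day prevalence, mu_log_daily (mu_j) the
    log-scale mean of daily travel activity among active travelers,
    sigma0 the intensity model's residual SD, and frequency_f = p_j/pi_j
    the mean daily rate of active travel among participants.
    """

    participation_pi: float
    prevalence_p: float
    mu_log_daily: float
    sigma0: float
    frequency_f: float

    def __post_init__(self) -> None:
        if not (0.0 < self.participation_pi < 1.0):
            raise ValueError("participation must lie strictly in (0, 1)")
        if not (0.0 < self.prevalence_p < 1.0):
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be nonnegative")
        if not np.isclose(
            self.frequency_f, self.prevalence_p / self.participation_pi, atol=1e-9
        ):
            raise ValueError("frequency must equal prevalence/participation")


def _response_series(records: pd.DataFrame, response: str) -> pd.Series:
    from hot_equity.cohort import FilterRules, compute_daily_travel_activity

    rules = FilterRules()
    ta_day = compute_daily_travel_activity(
        records["walk_hours_day"], records["cycle_hours_day"], rules
    )
    if response == "prevalence":
        return (ta_day > 0).astype(float)
    if response == "participation":
        return ((records["nwalk_week"] + records["ncycle_week"]) > 0).astype(float)
    return pd.Series(np.log(np.asarray(ta_day, dtype=float)), index=records.index)


def fit_model(
    records: pd.DataFrame, spec: ModelSpec, *, weighted: bool = False
) -> GlmFit:
    """Fit one of the three HOT regressions by maximum likelihood.

    Records with a missing value in any model covariate are dropped
    (complete-case, per-model).  For ``log_intensity`` only active
    travelers (daily travel activity > 0) enter the fit.

    Raises
    ------
    ModelError
        On separation or collinearity, naming the offending terms; or
        when no active travelers remain for the intensity model.
    """
    variables = spec.categorical_variables() + ["age"]
    df = records.dropna(subset=[v for v in variables if v in records.columns]).copy()

    if spec.response == "log_intensity":
        from hot_equity.cohort import FilterRules, compute_daily_travel_activity

        ta = compute_daily_travel_activity(
            df["walk_hours_day"], df["cycle_hours_day"], FilterRules()
        )
        df = df[np.asarray(ta) > 0]
        if len(df) == 0:
            raise ModelError("no active travelers: intensity model cannot be fit")

    df["_y"] = _response_series(df, spec.response)
    formula = spec.formula()

    try:
        if spec.family == "logistic":
            model = smf.glm(
                formula,
                data=df,
                family=sm.families.Binomial(),
                freq_weights=df["weight"].to_numpy() if weighted else None,
            )
            result = model.fit()
        else:
            if weighted:
                model = smf.wls(formula, data=df, weights=df["weight"].to_numpy())
            else:
                model = smf.ols(formula, data=df)
            result = model.fit()
    except Exception as exc:  # statsmodels raises several types here
        raise ModelError(f"{spec.response} model failed to fit: {exc}") from exc

    bad = [
        _plain_name(name)
        for name, est, se in zip(result.params.index, result.params, result.bse)
        if not (np.isfinite(est) and np.isfinite(se))
    ]
    if bad:
        raise ModelError(
            f"{spec.response} model is separated or collinear in terms: {bad}"
        )

    coefficients = {
        _plain_name(name): float(v) for name, v in result.params.items()
    }
    standard_errors = {
        _plain_name(name): float(v) for name, v in result.bse.items()
    }
    residual_sd = None
    if spec.family == "linear":
        residual_sd = float(np.sqrt(result.scale))  # df-corrected MSE

    fit = GlmFit(
        coefficients=coefficients,
        family=spec.family,
        n_used=int(result.nobs),
        residual_sd=residual_sd,
        spec=spec,
        age_mean=float(df["age"].mean()),
        standard_errors=standard_errors,
        _result=result,
    )
    logger.info(
        "%s model: n=%d, %d terms%s",
        spec.response,
        fit.n_used,
        len(coefficients),
        f", sigma0={residual_sd:.4f}" if residual_sd is not None else "",
    )
    return fit


_PATSY_FACTOR = re.compile(r"C\((\w+), Treatment\('([^']*)'\)\)\[T\.([^\]]*)\]")


def _plain_name(patsy_name: str) -> str:
    """Map a patsy column name to a plain ``var:level`` term key."""
    if patsy_name == "Intercept":
        return "intercept"
    parts = []
    for piece in patsy_name.split(":"):
        m = _PATSY_FACTOR.fullmatch(piece)
        parts.append(f"{m.group(1)}:{m.group(3)}" if m else piece)
    return "&".join(parts) if len(parts) > 1 else parts[0]


def _check_subgroup(fit: GlmFit, subgroup: SubgroupSpec) -> None:
    assert fit.spec is not None
    for var, level in subgroup.overrides:
        if var == "age":
            continue
        if var not in fit.spec.reference_levels:
            raise KeyError(f"variable {var!r} absent from model {fit.spec.response}")
        known = {
            key.split(":", 1)[1].split("&")[0]
            for key in fit.coefficients
            if key.startswith(f"{var}:")
        }
        known.add(fit.spec.reference_levels[var])
        if level not in known:
            raise KeyError(
                f"level {level!r} of {var!r} absent from model {fit.spec.response}"
            )


def subgroup_params(
    prevalence_fit: GlmFit,
    participation_fit: GlmFit,
    intensity_fit: GlmFit,
    subgroup: SubgroupSpec,
    *,
    age: float | None = None,
) -> SubgroupParams:
    """Extract the HOT parameters (pi_j, p_j, mu_j, sigma0, f_j) for a subgroup.

    Each model's linear predictor is evaluated at the reference profile
    with the subgroup's overrides applied (interaction terms follow
    automatically from the design).  Logistic predictors map to
    probabilities through the inverse logit; the intensity predictor is
    the log-scale daily mean.  ``age`` defaults to each fit's sample
    mean age.
    """
    from scipy.special import expit

    for fit, family in (
        (prevalence_fit, "logistic"),
        (participation_fit, "logistic"),
        (intensity_fit, "linear"),
    ):
        if fit.family != family:
            raise ValueError(f"expected a {family} fit, got {fit.family}")
        _check_subgroup(fit, subgroup)

    profile: dict[str, object] = subgroup.as_dict()
    if age is not None:
        profile["age"] = age

    p = float(expit(prevalence_fit.predict_linear(profile)))
    pi = float(expit(participation_fit.predict_linear(profile)))
    mu = intensity_fit.predict_linear(profile)
    if intensity_fit.residual_sd is None:
        raise ValueError("intensity fit carries no residual_sd")
    return SubgroupParams(
        participation_pi=pi,
        prevalence_p=p,
        mu_log_daily=mu,
        sigma0=intensity_fit.residual_sd,
        frequency_f=p / pi,
    )
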