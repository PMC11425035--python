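"""Synthetic household-travel-survey microdata with known ground truth.

Generates person-level records shaped like a one-day US household travel
survey: household clustering, survey weights, Table-1-style social and
environmental covariates, a weekly-participation Bernoulli layer, a
daily-frequency layer, and log-normal daily travel-activity intensities
— all driven by known logistic/linear coefficient maps so that every
downstream estimator can be checked against the generating truth.

The generative model per person i:

* weekly participation  ~ Bernoulli(pi_i),  pi_i = expit(x_i' b_part)
* survey-day activity | participant ~ Bernoulli(f_i),  f_i = p_i / pi_i
  with p_i = expit(x_i' b_prev)   (so the marginal survey-day prevalence
  is exactly p_i)
* daily travel activity | active ~ LogNormal(x_i' b_int, sigma0)
  split into walking and cycling hours by a uniform proportion so that
  3*walk_hours + 6*cycle_hours recovers the latent MET-hour total
* weekly trip counts: participants take 1 + Poisson(lambda) trips
  (guaranteeing at least one), non-participants take none.

Coefficient maps are keyed by ``intercept``, ``age`` (per decade,
centered at age 40) and ``variable:level``; unnamed terms are zero.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from hot_equity.models import DEFAULT_REFERENCE_LEVELS, SubgroupParams, SubgroupSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: Category levels and default probabilities, following the covariate
#: structure of a large US metropolitan travel-survey sample (shares of
#: the 2017 survey year, renormalized).
DEFAULT_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.53, "male": 0.47},
    "race": {
        "amerind": 0.005,
        "asian": 0.088,
        "black": 0.084,
        "multiple": 0.031,
        "pacific": 0.003,
        "other": 0.033,
        "white": 0.756,
    },
    "hispanic": {"no": 0.88, "yes": 0.12},
    "income_bracket": {
        "lt10k": 0.032,
        "10-15k": 0.025,
        "15-25k": 0.048,
        "25-35k": 0.056,
        "35-50k": 0.084,
        "50-75k": 0.150,
        "75-100k": 0.150,
        "100k+": 0.455,
    },
    "education": {
        "lt_highschool": 0.025,
        "highschool": 0.143,
        "some_college": 0.272,
        "bachelors": 0.308,
        "graduate": 0.252,
    },
    "pop_density_bin": {
        "0-99": 0.027,
        "100-499": 0.086,
        "500-999": 0.063,
        "1000-1999": 0.115,
        "2000-3999": 0.210,
        "4000-9999": 0.341,
        "10000-24999": 0.115,
        "25000+": 0.043,
    },
    "n_cars": {"0": 0.036, "1": 0.201, "2": 0.432, "3+": 0.331},
    "state": {"CA": 0.34, "NY": 0.21, "TX": 0.18, "WI": 0.13, "GA": 0.10, "AZ": 0.04},
    "season": {"winter": 0.25, "spring": 0.25, "summer": 0.25, "fall": 0.25},
}

#: Household-level variables shared by all members of a household.
HOUSEHOLD_VARIABLES = ("income_bracket", "n_cars", "pop_density_bin", "state", "season")
#: Person-level variables.
PERSON_VARIABLES = ("sex", "race", "hispanic", "education")

#: Covariate fields subject to item nonresponse.
MISSING_CANDIDATE_FIELDS = (
    "sex",
    "race",
    "hispanic",
    "income_bracket",
    "education",
    "pop_density_bin",
)

# Default truth coefficients.  Calibrated so the implied population-level
# rates match a 2017-style metropolitan survey: overall prevalence ~0.20,
# overall participation ~0.75, reference-profile participation 0.65,
# reference daily frequency ~0.16 and reference weekly intensity
# ~2.6 MET-hr/week at sigma0 = 0.8.  Non-reference effects echo the
# qualitative pattern of US metropolitan travel surveys: strong positive
# effects of carlessness and density, positive education/income
# gradients, lower activity among Black, Asian and Hispanic groups.
DEFAULT_PARTICIPATION_COEFS: dict[str, float] = {
    "intercept": 0.619,
    "sex:female": -0.04,
    "race:black": -0.18,
    "race:asian": -0.42,
    "hispanic:yes": -0.20,
    "education:lt_highschool": -0.10,
    "education:some_college": 0.20,
    "education:bachelors": 0.45,
    "education:graduate": 0.74,
    "income_bracket:lt10k": 0.15,
    "income_bracket:25-35k": -0.15,
    "income_bracket:100k+": 0.25,
    "n_cars:0": 1.37,
    "n_cars:1": 0.40,
    "n_cars:3+": -0.15,
    "pop_density_bin:0-99": -0.50,
    "pop_density_bin:100-499": -0.40,
    "pop_density_bin:500-999": -0.30,
    "pop_density_bin:1000-1999": -0.15,
    "pop_density_bin:4000-9999": 0.20,
    "pop_density_bin:10000-24999": 0.55,
    "pop_density_bin:25000+": 0.97,
}

DEFAULT_PREVALENCE_COEFS: dict[str, float] = {
    "intercept": -2.125,
    "sex:female": -0.02,
    "race:black": -0.35,
    "race:asian": -0.40,
    "hispanic:yes": -0.25,
    "education:lt_highschool": -0.10,
    "education:some_college": 0.25,
    "education:bachelors": 0.50,
    "education:graduate": 0.80,
    "income_bracket:lt10k": 0.25,
    "income_bracket:25-35k": -0.15,
    "income_bracket:100k+": 0.30,
    "n_cars:0": 1.60,
    "n_cars:1": 0.45,
    "n_cars:3+": -0.20,
    "pop_density_bin:0-99": -0.60,
    "pop_density_bin:100-499": -0.50,
    "pop_density_bin:500-999": -0.35,
    "pop_density_bin:1000-1999": -0.20,
    "pop_density_bin:4000-9999": 0.25,
    "pop_density_bin:10000-24999": 0.65,
    "pop_density_bin:25000+": 1.00,
}

DEFAULT_INTENSITY_COEFS: dict[str, float] = {
    # log MET-hr/day scale
    "intercept": 0.47,
    "sex:female": -0.12,
    "race:black": -0.19,
    "hispanic:yes": -0.10,
    "education:graduate": 0.48,
    "income_bracket:100k+": 0.58,
    "n_cars:0": 0.78,
    "pop_density_bin:25000+": 0.62,
}


def _validate_probs(category_probs: dict[str, dict[str, float]]) -> None:
    for var, probs in category_probs.items():
        total = float(sum(probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"probabilities for {var!r} sum to {total}, expected 1"
            )
        if any(p < 0 for p in probs.values()):
            raise ConfigError(f"negative probability for {var!r}")


def _normalized(probs: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    out = {}
    for var, p in probs.items():
        total = sum(p.values())
        out[var] = {k: v / total for k, v in p.items()}
    return out


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    ``category_probs`` gives the multinomial level probabilities per
    covariate; the truth coefficient maps (log-odds scale for
    participation/prevalence, log MET-hr/day for intensity) define the
    ground-truth generative model; ``sigma0_true`` is the log-scale
    residual SD of daily intensity.  Weights are log-normal with mean 1
    and log-scale SD ``weight_lognormal_sd``.  ``year_mode`` 2009
    additionally copies the household respondent's race and Hispanic
    status to every household member, as the 2009 survey instrument did.
    """

    n_households: int = 10_000
    mean_household_adults: float = 1.7
    year_mode: int = 2017
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: _normalized(DEFAULT_CATEGORY_PROBS)
    )
    truth_participation_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPATION_COEFS)
    )
    truth_prevalence_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_COEFS)
    )
    truth_intensity_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_COEFS)
    )
    sigma0_true: float = 0.8
    weight_lognormal_sd: float = 0.5
    missing_rate: float = 0.005
    msa_over_1m_prob: float = 0.85
    trip_rate_lambda: float = 2.0
    walk_trip_share: float = 0.7
    age_low: int = 18
    age_high: int = 84
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ConfigError("n_households must be positive")
        if self.mean_household_adults < 1:
            raise ConfigError("mean_household_adults must be at least 1")
        if self.year_mode not in (2009, 2017):
            raise ConfigError("year_mode must be 2009 or 2017")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigError("missing_rate must lie in [0, 1]")
        if self.sigma0_true < 0 or self.weight_lognormal_sd < 0:
            raise ConfigError("scale parameters must be nonnegative")
        _validate_probs(self.category_probs)
        for name, coefs in self._coef_maps().items():
            for term in coefs:
                self._validate_term(term, name)

    def _coef_maps(self) -> dict[str, dict[str, float]]:
        return {
            "participation": self.truth_participation_coefs,
            "prevalence": self.truth_prevalence_coefs,
            "intensity": self.truth_intensity_coefs,
        }

    def _validate_term(self, term: str, map_name: str) -> None:
        if term in ("intercept", "age"):
            return
        var, _, level = term.partition(":")
        if not level or var not in self.category_probs:
            raise ConfigError(f"unknown term {term!r} in {map_name} coefficients")
        if level not in self.category_probs[var]:
            raise ConfigError(
                f"unknown level {level!r} of {var!r} in {map_name} coefficients"
            )

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)


def _linear_predictor(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Evaluate intercept + age effect + categorical effects per row."""
    lp = np.full(len(df), coefs.get("intercept", 0.0))
    if "age" in coefs:
        lp = lp + coefs["age"] * (df["age"].to_numpy(float) - 40.0) / 10.0
    by_var: dict[str, dict[str, float]] = {}
    for term, beta in coefs.items():
        if term in ("intercept", "age"):
            continue
        var, _, level = term.partition(":")
        by_var.setdefault(var, {})[level] = beta
    for var, level_map in by_var.items():
        lp = lp + df[var].map(level_map).fillna(0.0).to_numpy(float)
    return lp


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic person table (one row per adult).

    Household members share the household-level variables (income, cars,
    density, state, season, metro flag); covariate draws follow
    ``category_probs``; the activity layers follow the module's
    generative model.  Reproducible: the same config and seed give
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n_hh = config.n_households
    hh_size = 1 + rng.poisson(config.mean_household_adults - 1.0, n_hh)
    n = int(hh_size.sum())
    hh_index = np.repeat(np.arange(n_hh), hh_size)

    def draw(var: str, size: int) -> np.ndarray:
        probs = config.category_probs[var]
        levels = np.array(list(probs.keys()), dtype=object)
        return rng.choice(levels, size=size, p=np.array(list(probs.values())))

    hh_cols = {var: draw(var, n_hh) for var in HOUSEHOLD_VARIABLES}
    msa_hh = rng.random(n_hh) < config.msa_over_1m_prob

    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": hh_index,
        }
    )
    for var in HOUSEHOLD_VARIABLES:
        df[var] = hh_cols[var][hh_index]
    df["msa_over_1m"] = msa_hh[hh_index]

    for var in PERSON_VARIABLES:
        df[var] = draw(var, n)
    df["age"] = rng.integers(config.age_low, config.age_high + 1, n)

    if config.year_mode == 2009:
        # The 2009 instrument recorded race/Hispanic status for the
        # household respondent only, propagated to all members.
        first = np.zeros(n_hh, dtype=int)
        first[1:] = np.cumsum(hh_size)[:-1]
        for var in ("race", "hispanic"):
            df[var] = df[var].to_numpy()[first][hh_index]

    sd = config.weight_lognormal_sd
    df["weight"] = (
        rng.lognormal(-0.5 * sd * sd, sd, n) if sd > 0 else np.ones(n)
    )

    pi = expit(_linear_predictor(df, config.truth_participation_coefs))
    p = expit(_linear_predictor(df, config.truth_prevalence_coefs))
    freq = p / pi
    n_clipped = int((freq > 1).sum())
    if n_clipped:
        logger.warning(
            "prevalence exceeds participation for %d persons; frequency clipped to 1",
            n_clipped,
        )
        freq = np.minimum(freq, 1.0)

    participant = rng.random(n) < pi
    active_day = participant & (rng.random(n) < freq)

    mu = _linear_predictor(df, config.truth_intensity_coefs)
    ta_latent = np.where(
        active_day, np.exp(rng.normal(mu, config.sigma0_true)), 0.0
    )
    # Split the latent MET-hr total between modes: a uniform proportion r
    # of the MET-hours is walking (3 MET), the rest cycling (6 MET), so
    # 3*walk_hours + 6*cycle_hours == ta_latent exactly.
    r = rng.random(n)
    df["walk_hours_day"] = np.where(active_day, r * ta_latent / 3.0, 0.0)
    df["cycle_hours_day"] = np.where(active_day, (1 - r) * ta_latent / 6.0, 0.0)

    total_trips = np.where(participant, 1 + rng.poisson(config.trip_rate_lambda, n), 0)
    nwalk = rng.binomial(total_trips, config.walk_trip_share)
    df["nwalk_week"] = nwalk
    df["ncycle_week"] = total_trips - nwalk

    missing_sets = [set() for _ in range(n)]
    if config.missing_rate > 0:
        for fieldname in MISSING_CANDIDATE_FIELDS:
            mask = rng.random(n) < config.missing_rate
            if mask.any():
                df.loc[mask, fieldname] = pd.NA
                for i in np.flatnonzero(mask):
                    missing_sets[i].add(fieldname)
    df["missing_fields"] = [";".join(sorted(s)) for s in missing_sets]

    logger.info(
        "generated %d persons in %d households (year_mode=%d, seed=%d)",
        n,
        n_hh,
        config.year_mode,
        config.seed,
    )
    return df


def ground_truth_params(
    config: GeneratorConfig,
    subgroup: SubgroupSpec,
    *,
    age: float = 40.0,
) -> SubgroupParams:
    """Exact HOT parameters implied by the truth coefficient maps.

    Evaluates the three truth linear predictors at the reference profile
    with the subgroup's overrides applied (age defaults to the centering
    age, 40, where the age term vanishes).  Serves as the oracle for
    parameter-recovery tests.
    """
    profile = dict(config.reference_levels)
    for var, level in subgroup.as_dict().items():
        if var not in config.category_probs:
            raise ConfigError(f"unknown subgroup variable {var!r}")
        if level not in config.category_probs[var]:
            raise ConfigError(f"unknown level {level!r} of subgroup variable {var!r}")
        profile[var] = level

    row = pd.DataFrame([{**profile, "age": age}])
    pi = float(expit(_linear_predictor(row, config.truth_participation_coefs))[0])
    p = float(expit(_linear_predictor(row, config.truth_prevalence_coefs))[0])
    mu = float(_linear_predictor(row, config.truth_intensity_coefs)[0])
    return SubgroupParams(
        participation_pi=pi,
        prevalence_p=p,
        mu_log_daily=mu,
        sigma0=config.sigma0_true,
        frequency_f=p / pi,
    )


#: Column order of the person-table CSV dialect.
PERSON_COLUMNS = (
    "person_id",
    "household_id",
    "weight",
    "sex",
    "age",
    "race",
    "hispanic",
    "income_bracket",
    "education",
    "pop_density_bin",
    "n_cars",
    "state",
    "season",
    "msa_over_1m",
    "walk_hours_day",
    "cycle_hours_day",
    "nwalk_week",
    "ncycle_week",
    "missing_fields",
)


def write_persons(df: pd.DataFrame, path) -> None:
    """Write the person table as CSV; missing values become empty cells."""
    df.loc[:, PERSON_COLUMNS].to_csv(path, index=False)


def read_persons(path) -> pd.DataFrame:
    """Read a person-table CSV written by :func:`write_persons`."""
    df = pd.read_csv(
        path,
        dtype={"n_cars": str, "missing_fields": str},
        keep_default_na=True,
        na_values=[""],
    )
    df["missing_fields"] = df["missing_fields"].fillna("")
    df["msa_over_1m"] = df["msa_over_1m"].astype(bool)
    return df
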