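import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hot_equity.models import ModelSpec
from hot_equity.synthetic import GeneratorConfig, generate_population

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Truth coefficient maps restricted to a compact covariate set, so that
#: a reduced regression model is correctly specified for recovery tests.
COMPACT_PARTICIPATION = {
    "intercept": 0.619,
    "sex:female": -0.10,
    "n_cars:0": 1.2,
    "n_cars:1": 0.35,
    "n_cars:3+": -0.15,
    "education:graduate": 0.6,
    "education:bachelors": 0.3,
    "education:some_college": 0.15,
    "education:lt_highschool": -0.1,
}
COMPACT_PREVALENCE = {
    "intercept": -1.41,
    "sex:female": -0.08,
    "n_cars:0": 1.4,
    "n_cars:1": 0.4,
    "n_cars:3+": -0.2,
    "education:graduate": 0.7,
    "education:bachelors": 0.35,
    "education:some_college": 0.18,
    "education:lt_highschool": -0.1,
}
COMPACT_INTENSITY = {
    "intercept": 0.30,
    "sex:female": -0.12,
    "n_cars:0": 0.6,
    "education:graduate": 0.4,
}
COMPACT_TERMS = ("sex", "age", "n_cars", "education")


def compact_config(seed: int = 0, n_households: int = 4000, **kwargs) -> GeneratorConfig:
    defaults = dict(
        n_households=n_households,
        truth_participation_coefs=dict(COMPACT_PARTICIPATION),
        truth_prevalence_coefs=dict(COMPACT_PREVALENCE),
        truth_intensity_coefs=dict(COMPACT_INTENSITY),
        sigma0_true=0.8,
        missing_rate=0.0,
        msa_over_1m_prob=1.0,
        age_low=19,
        age_high=65,
        seed=seed,
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


def compact_model_spec(response: str) -> ModelSpec:
    return ModelSpec(response=response, terms=COMPACT_TERMS)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240805)


@pytest.fixture(scope="session")
def default_population():
    """A moderately sized population under the package's default conditions."""
    return generate_population(GeneratorConfig(n_households=6000, seed=11))


@pytest.fixture(scope="session")
def compact_fits():
    """Three fits of the compact model on one compact synthetic cohort."""
    from hot_equity.models import fit_model

    cfg = compact_config(seed=5, n_households=15_000)
    df = generate_population(cfg)
    fits = {
        response: fit_model(df, compact_model_spec(response))
        for response in ("prevalence", "participation", "log_intensity")
    }
    return cfg, df, fits
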