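"""HOT comparative risk assessment for active-travel physical activity.

Each subgroup's travel activity is modelled as a zero-inflated
log-normal mixture on the weekly MET-hour scale: with probability
1 - pi the person does no active travel; otherwise weekly travel
activity is log-normal.  The log-scale subgroup parameters
(mu_j, sigma0) from the intensity regression are mapped to linear-scale
daily moments

    mu*_j    = exp(mu_j + sigma0^2/2)
    sigma*_j = sqrt((exp(sigma0^2) - 1) * exp(2*mu_j + sigma0^2))

and scaled to a weekly rate mu'_j = 7 f_j mu*_j, sigma'_j = 7 f_j sigma*_j
with f_j = p_j/pi_j the daily frequency of active travel.

The risk assessment simulates travel activity for the subgroup and the
reference group, adds the elementwise difference to a simulated baseline
leisure-time physical-activity vector PA_0 (clamping negatives at zero),
extracts m evenly spaced quantiles of PA_j and PA_0, and evaluates a
piecewise-linear exposure-response curve R for all-cause mortality:

    rho_j = sum_l R(q_l^j) / sum_l R(q_l^0) - 1,

the population attributable fraction — the proportional change in
expected mortality risk if the population's activity distribution
shifted from reference to subgroup.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from hot_equity.models import SubgroupParams


@dataclass
class LinearMoments:
    """Mean and SD of daily travel activity on the linear MET-hr/day scale."""

    mean_daily: float
    sd_daily: float

    def __post_init__(self) -> None:
        if self.mean_daily < 0 or self.sd_daily < 0:
            raise ValueError("moments must be nonnegative")


@dataclass
class WeeklyMixture:
    """Zero-inflated log-normal travel activity on the weekly scale.

    With probability 1 - participation_pi activity is zero; otherwise it
    is log-normal with linear-scale mean ``mean_weekly`` and SD
    ``sd_weekly`` (MET-hr/week).
    """

    participation_pi: float
    mean_weekly: float
    sd_weekly: float

    def __post_init__(self) -> None:
        if not 0 <= self.participation_pi <= 1:
            raise ValueError("participation must lie in [0, 1]")
        if self.mean_weekly < 0 or self.sd_weekly < 0:
            raise ValueError("weekly moments must be nonnegative")


@dataclass
class ExposureResponse:
    """Piecewise-linear relative-risk curve over weekly physical activity.

    ``knots`` are (exposure MET-hr/week, relative risk) pairs with
    strictly increasing exposures starting at 0, relative risk 1 at zero
    exposure, and non-increasing risk; the curve is constant beyond the
    last knot.
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        self.knots = tuple((float(x), float(r)) for x, r in self.knots)
        xs = [x for x, _ in self.knots]
        rs = [r for _, r in self.knots]
        if not xs or xs[0] != 0:
            raise ValueError("knots must start at exposure 0")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("knot exposures must be strictly increasing")
        if abs(rs[0] - 1.0) > 1e-12:
            raise ValueError("relative risk at zero exposure must be 1")
        if any(r <= 0 for r in rs):
            raise ValueError("relative risks must be positive")
        if any(b > a for a, b in zip(rs, rs[1:])):
            raise ValueError("relative risk must be non-increasing")

    @classmethod
    def from_csv(cls, path) -> "ExposureResponse":
        df = pd.read_csv(path, comment="#")
        return cls(tuple(zip(df["exposure_met_hr_week"], df["relative_risk"])))


@dataclass
class BaselinePA:
    """Baseline leisure-time physical-activity distribution (MET-hr/week).

    Either an empirical quantile table (probability -> MET-hr/week,
    sampled by inverse-CDF interpolation) or a point mass.
    """

    kind: str
    probabilities: np.ndarray | None = None
    values: np.ndarray | None = None
    point: float | None = None

    @classmethod
    def from_quantiles(cls, probabilities, values) -> "BaselinePA":
        p = np.asarray(probabilities, dtype=float)
        v = np.asarray(values, dtype=float)
        if p.shape != v.shape or p.ndim != 1 or len(p) < 2:
            raise ValueError("need matching 1-d probability and value arrays")
        if np.any(np.diff(p) <= 0) or p[0] < 0 or p[-1] > 1:
            raise ValueError("probabilities must be increasing within [0, 1]")
        if np.any(np.diff(v) < 0) or np.any(v < 0):
            raise ValueError("quantiles must be non-decreasing and non-negative")
        return cls(kind="quantiles", probabilities=p, values=v)

    @classmethod
    def point_mass(cls, value: float) -> "BaselinePA":
        if value < 0:
            raise ValueError("physical activity cannot be negative")
        return cls(kind="point_mass", point=float(value))

    @classmethod
    def from_csv(cls, path) -> "BaselinePA":
        df = pd.read_csv(path, comment="#")
        return cls.from_quantiles(df["probability"], df["met_hr_week"])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point_mass":
            return np.full(n, self.point)
        u = rng.random(n)
        return np.interp(u, self.probabilities, self.values)


@dataclass
class PafResult:
    """Outcome of one comparative risk assessment."""

    subgroup_id: str
    overall_ta_reference: float
    overall_ta_subgroup: float
    delta_ta_pct: float
    paf: float
    n_sim: int
    n_quantiles: int
    seed: int

    def __post_init__(self) -> None:
        expected = 100.0 * (self.overall_ta_subgroup / self.overall_ta_reference - 1.0)
        if abs(self.delta_ta_pct - expected) > 1e-9:
            raise ValueError("delta_ta_pct inconsistent with overall TA values")


def lognormal_linear_moments(mu_log: float, sigma0: float) -> LinearMoments:
    """Linear-scale mean/SD of LogNormal(mu_log, sigma0) daily activity."""
    if sigma0 < 0:
        raise ValueError("sigma0 must be nonnegative")
    mean = float(np.exp(mu_log + 0.5 * sigma0**2))
    var = (np.exp(sigma0**2) - 1.0) * np.exp(2.0 * mu_log + sigma0**2)
    return LinearMoments(mean_daily=mean, sd_daily=float(np.sqrt(var)))


def weekly_scale(
    moments: LinearMoments, frequency_f: float, participation_pi: float
) -> WeeklyMixture:
    """Scale daily moments to the weekly rate: mu' = 7 f mu*, sigma' = 7 f sigma*."""
    if not 0 <= frequency_f <= 1:
        raise ValueError("frequency must lie in [0, 1]")
    if not 0 < participation_pi < 1:
        raise ValueError("participation must lie strictly in (0, 1)")
    return WeeklyMixture(
        participation_pi=participation_pi,
        mean_weekly=7.0 * frequency_f * moments.mean_daily,
        sd_weekly=7.0 * frequency_f * moments.sd_daily,
    )


def sample_travel_activity(
    mix: WeeklyMixture, n_sim: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw weekly travel activity from the zero-inflated log-normal mixture.

    Each draw is zero with probability 1 - pi; otherwise log-normal with
    log-scale parameters moment-matched to (mean_weekly, sd_weekly):
    s^2 = ln(1 + (sd/mean)^2), m = ln(mean) - s^2/2.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if mix.participation_pi == 0:
        return np.zeros(n_sim)
    if mix.mean_weekly == 0:
        if mix.sd_weekly > 0:
            raise ValueError("cannot moment-match sd > 0 with mean 0")
        return np.zeros(n_sim)

    active = rng.random(n_sim) < mix.participation_pi
    if mix.sd_weekly == 0:
        draws = np.full(n_sim, mix.mean_weekly)
    else:
        s2 = np.log1p((mix.sd_weekly / mix.mean_weekly) ** 2)
        m = np.log(mix.mean_weekly) - 0.5 * s2
        draws = rng.lognormal(m, np.sqrt(s2), n_sim)
    return np.where(active, draws, 0.0)


def shift_baseline(pa0, ta_subgroup, ta_reference) -> np.ndarray:
    """PA_j = PA_0 + (TA_j - TA_0), clamped below at zero."""
    pa0 = np.asarray(pa0, dtype=float)
    ta_s = np.asarray(ta_subgroup, dtype=float)
    ta_r = np.asarray(ta_reference, dtype=float)
    if not pa0.shape == ta_s.shape == ta_r.shape:
        raise ValueError("vectors must have equal length")
    return np.maximum(pa0 + ta_s - ta_r, 0.0)


def evenly_spaced_quantiles(values, m: int) -> np.ndarray:
    """m quantiles at midpoint probabilities (l - 0.5)/m, l = 1..m."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if m < 2:
        raise ValueError("m must be at least 2")
    probs = (np.arange(1, m + 1) - 0.5) / m
    # inverted-CDF quantiles: order statistic at ceil(p*n), so a sample
    # evaluated on its own midpoint grid reproduces the sorted values
    return np.quantile(values, probs, method="inverted_cdf")


def exposure_response_eval(er: ExposureResponse, x) -> float | np.ndarray:
    """Relative risk at exposure x: linear interpolation between knots,
    constant beyond the last knot."""
    xs = np.array([k[0] for k in er.knots])
    rs = np.array([k[1] for k in er.knots])
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("exposure must be nonnegative")
    out = np.interp(xv, xs, rs)
    return float(out) if out.ndim == 0 else out


def compute_paf(q_subgroup, q_reference, er: ExposureResponse) -> float:
    """rho = sum R(q^j) / sum R(q^0) - 1 over equal-length quantile vectors."""
    qs = np.asarray(q_subgroup, dtype=float)
    qr = np.asarray(q_reference, dtype=float)
    if qs.shape != qr.shape:
        raise ValueError("quantile vectors must have equal length")
    num = float(np.sum(exposure_response_eval(er, qs)))
    den = float(np.sum(exposure_response_eval(er, qr)))
    if den == 0:
        raise ValueError("zero total reference risk")
    return num / den - 1.0


def overall_travel_activity(participation_pi: float, weekly_intensity: float) -> float:
    """Population mean travel activity: participation times intensity."""
    if participation_pi < 0 or participation_pi > 1 or weekly_intensity < 0:
        raise ValueError("participation in [0,1] and intensity >= 0 required")
    return participation_pi * weekly_intensity


def deaths_equivalent(paf: float, annual_deaths: int) -> int:
    """Deaths averted (or added): paf x annual deaths, nearest integer."""
    if annual_deaths < 0:
        raise ValueError("annual_deaths must be nonnegative")
    return int(
        Decimal(paf * annual_deaths).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding as used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _stream_seed(seed: int, tag: str, *values: float) -> np.random.Generator:
    """Derive a substream from (seed, tag, parameter values).

    Groups with identical parameters get identical streams (so a
    subgroup equal to the reference yields PAF exactly 0 under the same
    seed) while distinct parameters give independent streams.
    """
    h = hashlib.sha256(
        (tag + "|" + "|".join(np.float64(v).hex() for v in values)).encode()
    )
    entropy = int.from_bytes(h.digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, entropy]))


def subgroup_mixture(params: SubgroupParams) -> WeeklyMixture:
    """Weekly travel-activity mixture implied by subgroup parameters."""
    moments = lognormal_linear_moments(params.mu_log_daily, params.sigma0)
    return weekly_scale(moments, params.frequency_f, params.participation_pi)


def run_cra(
    params_subgroup: SubgroupParams,
    params_reference: SubgroupParams,
    er: ExposureResponse,
    baseline: BaselinePA,
    n_sim: int = 1_000_000,
    m: int = 10_000,
    seed: int = 0,
    *,
    subgroup_id: str = "",
    common_random_numbers: bool = False,
) -> PafResult:
    """Full comparative risk assessment for one subgroup vs the reference.

    Simulates ``n_sim`` draws of weekly travel activity for both groups,
    shifts the simulated baseline physical activity by their elementwise
    difference (clamped at zero), extracts ``m`` evenly spaced quantiles
    of the shifted and baseline distributions, and evaluates the
    population attributable fraction through the exposure-response
    curve.  The subgroup and reference draws are independent unless
    ``common_random_numbers`` pairs them for variance reduction.
    """
    mix_s = subgroup_mixture(params_subgroup)
    mix_r = subgroup_mixture(params_reference)

    if common_random_numbers:
        rng = _stream_seed(seed, "ta-crn")
        u = rng.random(n_sim)
        z = rng.standard_normal(n_sim)

        def paired_draw(mix: WeeklyMixture) -> np.ndarray:
            if mix.mean_weekly == 0:
                if mix.sd_weekly > 0:
                    raise ValueError("cannot moment-match sd > 0 with mean 0")
                return np.zeros(n_sim)
            if mix.sd_weekly == 0:
                draws = np.full(n_sim, mix.mean_weekly)
            else:
                s2 = np.log1p((mix.sd_weekly / mix.mean_weekly) ** 2)
                draws = np.exp(np.log(mix.mean_weekly) - 0.5 * s2 + np.sqrt(s2) * z)
            return np.where(u < mix.participation_pi, draws, 0.0)

        ta_s, ta_r = paired_draw(mix_s), paired_draw(mix_r)
    else:
        ta_s = sample_travel_activity(
            mix_s,
            n_sim,
            _stream_seed(seed, "ta", mix_s.participation_pi, mix_s.mean_weekly, mix_s.sd_weekly),
        )
        ta_r = sample_travel_activity(
            mix_r,
            n_sim,
            _stream_seed(seed, "ta", mix_r.participation_pi, mix_r.mean_weekly, mix_r.sd_weekly),
        )

    pa0 = baseline.sample(n_sim, _stream_seed(seed, "baseline"))
    pa_j = shift_baseline(pa0, ta_s, ta_r)

    q_j = evenly_spaced_quantiles(pa_j, m)
    q_0 = evenly_spaced_quantiles(pa0, m)
    paf = compute_paf(q_j, q_0, er)

    ta_ref = overall_travel_activity(mix_r.participation_pi, mix_r.mean_weekly)
    ta_sub = overall_travel_activity(mix_s.participation_pi, mix_s.mean_weekly)
    return PafResult(
        subgroup_id=subgroup_id,
        overall_ta_reference=ta_ref,
        overall_ta_subgroup=ta_sub,
        delta_ta_pct=100.0 * (ta_sub / ta_ref - 1.0),
        paf=paf,
        n_sim=n_sim,
        n_quantiles=m,
        seed=seed,
    )


def default_exposure_response() -> ExposureResponse:
    """Packaged synthetic stand-in exposure-response curve.

    A constructed non-increasing piecewise-linear curve with the
    qualitative shape of cohort-derived leisure-time physical-activity
    hazard ratios (steep early benefit, flattening at high doses).  It
    is synthetic: it does not reproduce any published hazard-ratio
    fit.
    """
    path = resources.files("hot_equity.data") / "exposure_response_synthetic.csv"
    return ExposureResponse.from_csv(path)


def default_baseline_pa() -> BaselinePA:
    """Packaged synthetic stand-in baseline physical-activity distribution.

    A constructed quantile table for weekly leisure-time physical
    activity: about a quarter of the population inactive, a long
    right tail.  Synthetic: not estimated from any cohort.
    """
    path = resources.files("hot_equity.data") / "baseline_pa_synthetic.csv"
    return BaselinePA.from_csv(path)
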