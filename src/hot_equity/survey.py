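"""Survey-weighted estimation: proportions, frequency, design-adjusted tests.

Prevalence (the proportion reporting any walk/cycle trip on the survey
day) and participation (the proportion reporting at least one trip over
the past week) are estimated as weighted proportions with normal-
approximation confidence intervals on the effective sample size
n_eff = (sum w)^2 / sum w^2 (Kish).  Their ratio f = p/pi estimates the
mean daily frequency of active travel among participants.

The association screen is a Pearson chi-square on the weighted
contingency table deflated by the mean design effect of the level-wise
proportion estimates — a first-order analogue of a survey-design
adjusted chi-square test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ProportionEstimate:
    """A weighted proportion with its 95% interval and effective n."""

    estimate: float
    ci_low: float
    ci_high: float
    effective_n: float

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.estimate <= self.ci_high <= 1:
            raise ValueError("interval must satisfy 0 <= low <= estimate <= high <= 1")


def weighted_proportion(indicator, weights) -> ProportionEstimate:
    """Estimate a population proportion from a 0/1 indicator and weights.

    estimate = sum(w*x)/sum(w); the 95% Wald interval uses the effective
    sample size n_eff = (sum w)^2 / sum(w^2) and is truncated to [0, 1].
    """
    x = np.asarray(indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("indicator and weights must be 1-d and equal length")
    if len(x) < 2:
        raise ValueError("at least 2 records are required")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("indicator must be 0/1")

    p = float(np.sum(w * x) / np.sum(w))
    n_eff = float(np.sum(w) ** 2 / np.sum(w * w))
    se = np.sqrt(p * (1 - p) / n_eff)
    z = stats.norm.ppf(0.975)
    return ProportionEstimate(
        estimate=p,
        ci_low=max(0.0, p - z * se),
        ci_high=min(1.0, p + z * se),
        effective_n=n_eff,
    )


def frequency(prevalence: float, participation: float) -> float:
    """Mean daily frequency of active travel, f = prevalence/participation."""
    if participation == 0:
        raise ValueError("participation must be positive")
    f = prevalence / participation
    if f > 1:
        logger.warning(
            "estimated frequency %.3f exceeds 1 (estimation noise: "
            "prevalence above participation)",
            f,
        )
    return f


def design_adjusted_chisq(var_levels, outcome, weights) -> tuple[float, int, float]:
    """Design-effect-adjusted Pearson chi-square test of association.

    Builds the weighted levels-by-outcome contingency table (weighted
    cell proportions scaled back to the raw per-level counts), computes
    the Pearson X^2 statistic, and deflates it by the mean design effect
    deff_l = n_l / n_eff_l of the level-wise proportion estimates.
    With equal weights this reduces to the classical Pearson test.

    Returns (statistic, degrees of freedom, p-value); df = levels - 1
    for a binary outcome.
    """
    g = pd.Series(np.asarray(var_levels, dtype=object), name="level")
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(g) == len(y) == len(w)):
        raise ValueError("inputs must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")

    counts = np.empty((len(levels), 2))
    deffs = np.empty(len(levels))
    for i, level in enumerate(levels):
        mask = (g == level).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"need at least 2 records per level (level {level!r})")
        est = weighted_proportion(y[mask], w[mask])
        n_l = int(mask.sum())
        counts[i] = (n_l * est.estimate, n_l * (1 - est.estimate))
        deffs[i] = n_l / est.effective_n

    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table (zero margin)")

    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    x2 = float(np.sum((counts - expected) ** 2 / expected))

    x2_adj = x2 / float(np.mean(deffs))
    df = len(levels) - 1
    p = float(stats.chi2.sf(x2_adj, df))
    return x2_adj, df, p
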