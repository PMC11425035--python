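"""Cohort eligibility and quality filters for travel-survey microdata.

Reproduces the study-sample construction of a metropolitan active-travel
analysis: working-age adults (19-65 inclusive), households in
metropolitan areas over one million, removal of records missing data
needed for participation estimation, removal of states contributing
fewer than 150 households, and removal of outlying travel-activity
estimates (> 50 MET-hours/week on the weekly scale).

Daily travel activity is the MET-weighted one-day duration
T = alpha_w * walk_hours + alpha_c * cycle_hours with alpha_w = 3 MET
(walking) and alpha_c = 6 MET (cycling).  The weekly scale used by the
outlier rule is 7 * f * T with f the sample-level frequency of active
travel (prevalence/participation); a switch allows the cruder 7 * T
extrapolation instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fields whose absence disqualifies a record ("missing data needed for
#: participation estimates"): the survey weight, the weekly trip counts,
#: and every regression covariate.
REQUIRED_FIELDS = (
    "weight",
    "nwalk_week",
    "ncycle_week",
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
)


@dataclass
class FilterRules:
    """Eligibility thresholds and MET weights.

    age bounds are inclusive; ``max_weekly_travel_activity`` is in
    MET-hours/week; ``alpha_walk``/``alpha_cycle`` are the MET
    strenuousness of walking and cycling.
    """

    age_min: int = 19
    age_max: int = 65
    require_msa_over_1m: bool = True
    min_households_per_state: int = 150
    max_weekly_travel_activity: float = 50.0
    alpha_walk: float = 3.0
    alpha_cycle: float = 6.0

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be less than age_max")
        if min(
            self.min_households_per_state,
            self.max_weekly_travel_activity,
            self.alpha_walk,
            self.alpha_cycle,
        ) <= 0:
            raise ValueError("thresholds and MET weights must be positive")


@dataclass
class AttritionReport:
    """Record counts before and after each filter step, in order applied."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, records_in: int, records_out: int, households_out: int) -> None:
        if records_out > records_in:
            raise ValueError("a filter cannot add records")
        if self.steps and self.steps[-1][2] != records_in:
            raise ValueError("records_in must match the previous step's records_out")
        self.steps.append((name, records_in, records_out, households_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["filter_name", "records_in", "records_out", "households_out"],
        )


def compute_daily_travel_activity(
    walk_hours, cycle_hours, rules: FilterRules | None = None
):
    """Daily travel activity T = alpha_w*walk + alpha_c*cycle (MET-hr/day).

    Accepts scalars or array-likes; zero iff both durations are zero.
    """
    rules = rules or FilterRules()
    w = np.asarray(walk_hours, dtype=float)
    c = np.asarray(cycle_hours, dtype=float)
    if np.any(w < 0) or np.any(c < 0):
        raise ValueError("durations must be nonnegative")
    ta = rules.alpha_walk * w + rules.alpha_cycle * c
    return float(ta) if ta.ndim == 0 else ta


def _provisional_frequency(df: pd.DataFrame, rules: FilterRules) -> float:
    """Sample-level frequency f = prevalence/participation, weighted."""
    from hot_equity.survey import frequency, weighted_proportion

    ta = compute_daily_travel_activity(df["walk_hours_day"], df["cycle_hours_day"], rules)
    w = df["weight"].to_numpy(float)
    prev = weighted_proportion((np.asarray(ta) > 0).astype(float), w).estimate
    part = weighted_proportion(
        ((df["nwalk_week"] + df["ncycle_week"]) > 0).astype(float).to_numpy(), w
    ).estimate
    return frequency(prev, part)


def apply_filters(
    records: pd.DataFrame,
    rules: FilterRules | None = None,
    overall_frequency: float | None = None,
    *,
    outlier_rule: str = "scaled",
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the cohort filters in their fixed order and report attrition.

    Order: age window -> metro flag -> missing-data removal -> state
    minimum-household rule -> weekly travel-activity outlier rule.  The
    first two are record-local and commute; the state rule depends on
    the sample remaining after them.

    ``overall_frequency`` is the sample-level daily frequency f used to
    scale diary-day activity to the weekly scale for the outlier rule;
    when None it is estimated (weighted) from the pre-outlier-filter
    sample.  ``outlier_rule="unscaled"`` uses 7*T instead of 7*f*T.
    """
    rules = rules or FilterRules()
    if len(records) == 0:
        raise ValueError("no records to filter")
    if overall_frequency is not None and not 0 < overall_frequency <= 1:
        raise ValueError("overall_frequency must lie in (0, 1]")
    if outlier_rule not in ("scaled", "unscaled"):
        raise ValueError("outlier_rule must be 'scaled' or 'unscaled'")

    report = AttritionReport()
    df = records

    def _log_step(name: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        report.add(name, len(before), len(after), after["household_id"].nunique())
        logger.info("filter %-20s %7d -> %7d records", name, len(before), len(after))

    out = df[(df["age"] >= rules.age_min) & (df["age"] <= rules.age_max)]
    _log_step("age", df, out)
    df = out

    if rules.require_msa_over_1m:
        out = df[df["msa_over_1m"].astype(bool)]
    else:
        out = df
    _log_step("metro", df, out)
    df = out

    present = [f for f in REQUIRED_FIELDS if f in df.columns]
    keep = df[present].notna().all(axis=1)
    if "missing_fields" in df.columns:
        flagged = df["missing_fields"].fillna("").map(
            lambda s: bool(set(s.split(";")) & set(REQUIRED_FIELDS)) if s else False
        )
        keep &= ~flagged
    out = df[keep]
    _log_step("missing", df, out)
    df = out

    hh_per_state = df.groupby("state")["household_id"].nunique()
    good_states = hh_per_state[hh_per_state >= rules.min_households_per_state].index
    out = df[df["state"].isin(good_states)]
    _log_step("state_min_households", df, out)
    df = out
    if len(df) == 0:
        raise ValueError("no records survive the state filter")

    f = overall_frequency
    if outlier_rule == "scaled":
        if f is None:
            f = _provisional_frequency(df, rules)
        scale = 7.0 * f
    else:
        scale = 7.0
    ta = compute_daily_travel_activity(df["walk_hours_day"], df["cycle_hours_day"], rules)
    out = df[np.asarray(ta) * scale <= rules.max_weekly_travel_activity]
    _log_step("outlier", df, out)

    return out, report
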