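"""Survey-weighted prevalence and participation of active travel.

Estimates the overall and per-level weighted proportions with 95%
intervals, the frequency ratio f = prevalence/participation, and a
design-effect-adjusted chi-square screen of association for each
stratifying variable.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hot_equity.cohort import compute_daily_travel_activity
from hot_equity.survey import design_adjusted_chisq, frequency, weighted_proportion
from hot_equity.synthetic import read_persons

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")
VARIABLES = (
    "sex", "race", "hispanic", "income_bracket", "education",
    "pop_density_bin", "n_cars",
)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    tidy, tests = [], []
    for year in (2009, 2017):
        cohort = read_persons(SCRATCH / f"cohort_{year}.csv")
        ta = np.asarray(
            compute_daily_travel_activity(
                cohort["walk_hours_day"], cohort["cycle_hours_day"]
            )
        )
        prev_ind = (ta > 0).astype(float)
        part_ind = ((cohort["nwalk_week"] + cohort["ncycle_week"]) > 0).astype(float).to_numpy()
        w = cohort["weight"].to_numpy(float)

        overall = {}
        for measure, ind in (("prevalence", prev_ind), ("participation", part_ind)):
            est = weighted_proportion(ind, w)
            overall[measure] = est
            tidy.append(
                dict(variable="overall", level="overall", year=year, measure=measure,
                     estimate=est.estimate, ci_low=est.ci_low, ci_high=est.ci_high)
            )
            for var in VARIABLES:
                for level, sub in cohort.groupby(var):
                    mask = (cohort[var] == level).to_numpy()
                    e = weighted_proportion(ind[mask], w[mask])
                    tidy.append(
                        dict(variable=var, level=level, year=year, measure=measure,
                             estimate=e.estimate, ci_low=e.ci_low, ci_high=e.ci_high)
                    )
            for var in VARIABLES:
                ok = cohort[var].notna().to_numpy()
                stat, df_, p = design_adjusted_chisq(
                    cohort[var].to_numpy()[ok], ind[ok], w[ok]
                )
                tests.append(
                    dict(variable=var, year=year, measure=measure,
                         statistic=stat, df=df_, neg_log10_p=-np.log10(max(p, 1e-300)))
                )
        f = frequency(overall["prevalence"].estimate, overall["participation"].estimate)
        print(
            f"{year}: prevalence {overall['prevalence'].estimate:.3f}, "
            f"participation {overall['participation'].estimate:.3f}, frequency {f:.3f}"
        )
    pd.DataFrame(tidy).to_csv(RESULTS / "weighted_estimates.csv", index=False)
    pd.DataFrame(tests).to_csv(RESULTS / "association_tests.csv", index=False)
    print(f"wrote {RESULTS / 'weighted_estimates.csv'} and {RESULTS / 'association_tests.csv'}")


if __name__ == "__main__":
    main()
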