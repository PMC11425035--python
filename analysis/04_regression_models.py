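"""Fit the three multivariate regressions per survey wave.

Logistic models for prevalence (any survey-day active travel) and
participation (any trip in the past week), and a linear model for log
daily travel activity among active travelers.  Writes the fitted
coefficients (JSON) and an odds-ratio / coefficient table (CSV).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hot_equity.models import ModelSpec, fit_model
from hot_equity.synthetic import read_persons

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for year in (2009, 2017):
        cohort = read_persons(SCRATCH / f"cohort_{year}.csv")
        for response in ("prevalence", "participation", "log_intensity"):
            fit = fit_model(cohort, ModelSpec(response=response))
            fit.to_json(RESULTS / f"model_{response}_{year}.json")
            for term, beta in fit.coefficients.items():
                se = fit.standard_errors[term]
                row = dict(year=year, model=response, term=term,
                           estimate=beta, se=se,
                           ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se)
                if fit.family == "logistic":
                    row["odds_ratio"] = float(np.exp(beta))
                rows.append(row)
            extra = (
                f", sigma0 = {fit.residual_sd:.3f}" if fit.residual_sd is not None else ""
            )
            print(f"{year} {response}: n = {fit.n_used:,}{extra}")
    pd.DataFrame(rows).to_csv(RESULTS / "coefficients.csv", index=False)
    print(f"wrote {RESULTS / 'coefficients.csv'}")


if __name__ == "__main__":
    main()
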