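"""Apply the cohort eligibility and quality filters to each survey wave.

Reports the attrition at every step (age 19-65, metro > 1M, missing
data, states under 150 households, > 50 MET-hr/week outliers) and writes
the filtered cohorts back to scratch/ for the downstream stages.
"""

from pathlib import Path

from hot_equity.cohort import apply_filters
from hot_equity.synthetic import read_persons, write_persons

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for year in (2009, 2017):
        src = SCRATCH / f"persons_{year}.csv"
        if not src.exists():
            raise SystemExit(f"{src} missing - run analysis/01_generate_survey.py first")
        persons = read_persons(src)
        cohort, attrition = apply_filters(persons)
        frame = attrition.to_frame()
        frame.to_csv(RESULTS / f"attrition_{year}.csv", index=False)
        write_persons(cohort, SCRATCH / f"cohort_{year}.csv")
        kept = len(cohort) / len(persons)
        print(f"{year}: {len(persons):,} -> {len(cohort):,} records ({kept:.1%} retained)")
        print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
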