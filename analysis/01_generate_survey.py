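"""Generate the two synthetic survey waves used throughout the analysis.

Emulates a 2009-style wave (household-respondent race propagation) and a
2017-style wave under the package's default ground-truth coefficients.
Person tables go to scratch/ (they are bulky, regenerable inputs); the
ground-truth subgroup parameters go to results/analysis/.
"""

import dataclasses
import json
from pathlib import Path

from hot_equity.report import DEFAULT_SUBGROUPS
from hot_equity.synthetic import GeneratorConfig, generate_population, ground_truth_params, write_persons

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")
N_HOUSEHOLDS = 20_000
SEEDS = {2009: 109, 2017: 117}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    truth = {}
    for year, seed in SEEDS.items():
        cfg = GeneratorConfig(n_households=N_HOUSEHOLDS, year_mode=year, seed=seed)
        df = generate_population(cfg)
        write_persons(df, SCRATCH / f"persons_{year}.csv")
        truth[year] = {
            sg.name: dataclasses.asdict(ground_truth_params(cfg, sg))
            for sg in DEFAULT_SUBGROUPS
        }
        print(
            f"{year}: {len(df):,} persons in {N_HOUSEHOLDS:,} households "
            f"(seed {seed}) -> {SCRATCH / f'persons_{year}.csv'}"
        )
    (RESULTS / "ground_truth_params.json").write_text(json.dumps(truth, indent=1))
    print(f"ground-truth subgroup parameters -> {RESULTS / 'ground_truth_params.json'}")


if __name__ == "__main__":
    main()
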