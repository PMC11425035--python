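"""Assembly of the subgroup parameter / health-impact report table.

One row per subgroup: participation, weekly intensity among active
travelers (mu'_j, MET-hr/week), daily frequency, overall travel
activity (participation x intensity), percent change in overall travel
activity versus the reference profile, and the population attributable
fraction for all-cause mortality (percent).  Values are rounded half-up
to 2 decimals at report time only.
"""

from __future__ import annotations

import pandas as pd

from hot_equity.cra import (
    BaselinePA,
    ExposureResponse,
    round_half_up,
    run_cra,
    subgroup_mixture,
)
from hot_equity.models import GlmFit, SubgroupParams, SubgroupSpec, subgroup_params

TABLE_COLUMNS = (
    "subgroup",
    "participation",
    "intensity_met_hr_week",
    "frequency",
    "overall_ta_met_hr_week",
    "delta_ta_pct",
    "paf_pct",
)


def subgroup_table(
    params_by_subgroup: dict[str, SubgroupParams],
    reference_id: str,
    er: ExposureResponse,
    baseline: BaselinePA,
    n_sim: int = 1_000_000,
    m: int = 10_000,
    seed: int = 0,
    *,
    rounded: bool = True,
) -> pd.DataFrame:
    """Run the CRA for every subgroup against the reference and tabulate."""
    if reference_id not in params_by_subgroup:
        raise KeyError(f"reference subgroup {reference_id!r} missing")
    ref = params_by_subgroup[reference_id]
    rows = []
    for name, params in params_by_subgroup.items():
        mix = subgroup_mixture(params)
        result = run_cra(
            params, ref, er, baseline, n_sim=n_sim, m=m, seed=seed, subgroup_id=name
        )
        row = {
            "subgroup": name,
            "participation": params.participation_pi,
            "intensity_met_hr_week": mix.mean_weekly,
            "frequency": params.frequency_f,
            "overall_ta_met_hr_week": result.overall_ta_subgroup,
            "delta_ta_pct": result.delta_ta_pct,
            "paf_pct": 100.0 * result.paf,
        }
        if rounded:
            row = {
                k: (round_half_up(v, 2) if isinstance(v, float) else v)
                for k, v in row.items()
            }
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def params_from_fits(
    prevalence_fit: GlmFit,
    participation_fit: GlmFit,
    intensity_fit: GlmFit,
    subgroups: list[SubgroupSpec],
) -> dict[str, SubgroupParams]:
    """Extract SubgroupParams for a list of subgroups from fitted models."""
    out: dict[str, SubgroupParams] = {}
    for sg in subgroups:
        out[sg.name or repr(sg.overrides)] = subgroup_params(
            prevalence_fit, participation_fit, intensity_fit, sg
        )
    return out


#: The study's seven single-variable contrast subgroups plus the reference.
DEFAULT_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec.reference(),
    SubgroupSpec.single("sex", "female", "female"),
    SubgroupSpec.single("race", "asian", "asian"),
    SubgroupSpec.single("race", "black", "black"),
    SubgroupSpec.single("hispanic", "yes", "hispanic"),
    SubgroupSpec.single("education", "graduate", "graduate_degree"),
    SubgroupSpec.single("income_bracket", "100k+", "highest_income"),
    SubgroupSpec.single("pop_density_bin", "25000+", "density_over_25k"),
    SubgroupSpec.single("n_cars", "0", "zero_cars"),
)
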