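"""Longitudinal behavior of the selected markers.

Baseline fast-vs-slow differences (exact Mann-Whitney) and random-slope /
random-intercept mixed models with age at first draw as a covariate.

Expected finding on the generator's truth: baseline levels differ between
groups while within-group slopes are indistinguishable from zero — the
planted group effects are constant over time.
"""

import json
from pathlib import Path

from als_proteome_state.differential import sample_groups
from als_proteome_state.preprocess import impute_protein_means
from als_proteome_state.synthetic_cohort import read_cohort
from als_proteome_state.trajectories import baseline_compare, fit_random_slope_model

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohorts"


def main() -> None:
    matrix, metadata = read_cohort(SCRATCH / "cohort_powered_preprocessed")
    markers = json.loads((OUT / "selection" / "selection.json").read_text())[
        "selected_proteins"
    ][:3]
    labels = sample_groups(metadata)
    meta = metadata[metadata["sample_id"].isin(labels.index)]
    sub = impute_protein_means(matrix.subset_proteins(markers))

    report = {}
    for m in markers:
        fit = fit_random_slope_model(
            sub.values.loc[m, meta["sample_id"]].to_numpy(),
            meta["months_from_baseline"].to_numpy(float),
            meta["patient_id"].to_numpy(),
            labels.loc[meta["sample_id"]].to_numpy(),
            meta["age_at_onset"].to_numpy(float),
        )
        base = meta[meta["visit_index"] == 0]
        p_base = baseline_compare(
            sub.values.loc[m, base["sample_id"]].to_numpy(),
            labels.loc[base["sample_id"]].to_numpy(),
        )
        report[m] = {
            "baseline_mw_p": round(p_base, 5),
            "slope_per_month": {g: round(v, 4) for g, v in fit.fixed_slope.items()},
            "slope_p": {g: round(v, 4) for g, v in fit.slope_p_value.items()},
        }
        print(f"{m}: baseline p={p_base:.2e}; slopes {report[m]['slope_per_month']} "
              f"(p {report[m]['slope_p']})")
    (OUT / "trajectories.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
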