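"""rdCV random-forest variable selection over the candidate panel.

Repeated double cross-validation with patient-stratified folds: the inner
loop drives recursive variable elimination, the outer loop scores held-out
samples. Consensus selection across repetitions yields the marker panel and
a swim-lane table of per-visit class probabilities.
"""

import json
from pathlib import Path

from als_proteome_state.muvr_select import RdCvConfig, rdcv_select, swim_lane_table
from als_proteome_state.differential import sample_groups
from als_proteome_state.preprocess import impute_protein_means
from als_proteome_state.synthetic_cohort import read_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohorts"
SEED = 11


def main() -> None:
    matrix, metadata = read_cohort(SCRATCH / "cohort_powered_preprocessed")
    panel = [
        p for p in (OUT / "differential" / "cohort_powered" / "panel.txt")
        .read_text().splitlines() if p
    ]
    labels = sample_groups(metadata)
    features = impute_protein_means(matrix.subset_proteins(panel)).values.T.loc[labels.index]
    patients = metadata.set_index("sample_id").loc[labels.index, "patient_id"]

    config = RdCvConfig(n_repetitions=5, n_outer_folds=5, n_inner_folds=4,
                        drop_fraction=0.3, n_trees=64, seed=SEED)
    result = rdcv_select(features, labels, config, patient_ids=patients)

    d = OUT / "selection"
    d.mkdir(exist_ok=True)
    (d / "selection.json").write_text(json.dumps({
        "selected_proteins": result.selected_proteins,
        "selection_frequency": result.selection_frequency.round(3).to_dict(),
        "n_misclassified": result.n_misclassified,
    }, indent=2))
    swim_lane_table(result, metadata).to_csv(d / "swim_lanes.tsv", sep="\t", index=False)
    print(f"selected {len(result.selected_proteins)} proteins "
          f"(top: {', '.join(result.selected_proteins[:5])}); "
          f"{result.n_misclassified} misclassified samples")


if __name__ == "__main__":
    main()
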