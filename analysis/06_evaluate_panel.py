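"""Logistic/ROC evaluation of the top three selected markers.

Fits a logistic panel score, computes AUC with a stratified 1000-sample
percentile bootstrap CI, and reports the Youden-optimal criterion with its
sensitivity and specificity, for the combined panel and each marker alone.
"""

import json
from pathlib import Path

import numpy as np

from als_proteome_state.differential import sample_groups
from als_proteome_state.panel_eval import evaluate_panel
from als_proteome_state.preprocess import impute_protein_means
from als_proteome_state.synthetic_cohort import read_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohorts"
SEED = 12


def main() -> None:
    matrix, metadata = read_cohort(SCRATCH / "cohort_powered_preprocessed")
    markers = json.loads((OUT / "selection" / "selection.json").read_text())[
        "selected_proteins"
    ][:3]
    labels = sample_groups(metadata)
    sub = impute_protein_means(matrix.subset_proteins(markers))
    X = sub.values.T.loc[labels.index].to_numpy()
    y = (labels == "fast").astype(int).to_numpy()

    report = {}
    rng = np.random.default_rng(SEED)
    for name, Xi in [("panel", X)] + [(m, X[:, [i]]) for i, m in enumerate(markers)]:
        r = evaluate_panel(Xi, y, n_boot=1000, seed=rng)
        report[name] = {
            "auc": round(r.auc, 3),
            "ci": [round(r.ci_low, 3), round(r.ci_high, 3)],
            "criterion": round(r.criterion, 3),
            "sensitivity": round(r.sensitivity, 3),
            "specificity": round(r.specificity, 3),
        }
        print(f"{name:10s} AUC {report[name]['auc']:.3f} "
              f"({report[name]['ci'][0]:.3f}-{report[name]['ci'][1]:.3f}) "
              f"criterion {report[name]['criterion']:.3f}")
    (OUT / "evaluation.json").write_text(json.dumps({"markers": markers,
                                                     "results": report}, indent=2))


if __name__ == "__main__":
    main()
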