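"""Repeated double cross-validation (rdCV) random-forest variable selection.

Mirrors the unbiased-variable-selection strategy used for biomarker panels:
an outer CV loop estimates prediction error on held-out samples while, within
each outer training set, an inner CV loop drives recursive variable
elimination (rank variables by random-forest importance, drop a fixed
fraction per step). The variable count minimizing inner misclassification
("min" model) is refit on the outer training set and applied to the outer
test fold. Selection frequencies and per-sample class probabilities are
aggregated over repetitions.

Because visits of one patient are strongly correlated, folds are stratified
by patient by default: all visits of a patient travel together, so a sample
is never predicted by a model trained on the same patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance


@dataclass(frozen=True)
class RdCvConfig:
    n_repetitions: int = 30
    n_outer_folds: int = 6
    n_inner_folds: int = 5
    drop_fraction: float = 0.2
    model_choice: str = "min"  # {min, mid, max}
    n_trees: int = 100
    seed: int = 0
    patient_stratified: bool = True
    importance: str = "impurity"  # {impurity, permutation}
    min_variables: int = 2

    def validate(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.model_choice not in ("min", "mid", "max"):
            raise ValueError("model_choice must be one of min/mid/max")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")


@dataclass
class SelectionResult:
    """Consensus panel and per-sample prediction summaries."""

    selected_proteins: list[str]
    selection_frequency: pd.Series  # fraction of repetitions selecting each protein
    per_repetition_sets: list[set[str]]
    per_sample_probability: pd.Series  # mean probability of the sample's own class
    misclassified: list[str]
    n_misclassified: int
    labels: pd.Series = field(default=None)


def _stratified_unit_folds(units, unit_labels, n_folds, rng):
    """Deal units (patients or samples) into folds, class-balanced."""
    folds: list[list] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in np.unique(unit_labels):
        members = [u for u, l in zip(units, unit_labels) if l == cls]
        if len(members) < n_folds:
            warnings.warn(
                f"class {cls!r} has {len(members)} units for {n_folds} folds; "
                "some folds will lack this class in the test split",
                stacklevel=3,
            )
        members = list(members)
        rng.shuffle(members)
        for i, u in enumerate(members):
            folds[(i + offset) % n_folds].append(u)
        offset += len(members)
    return [f for f in folds if f]


def _importance(clf, X_val, y_val, method, rng):
    if method == "impurity":
        return clf.feature_importances_
    r = permutation_importance(
        clf, X_val, y_val, n_repeats=5, random_state=int(rng.integers(2**31))
    )
    return r.importances_mean


def _eliminate(X, y, features, config, rng):
    """Inner-CV recursive elimination on one outer training set.

    Returns (best feature list per model_choice, dict count -> inner error).
    """
    units = np.unique(X.index.get_level_values("unit"))
    unit_label = {u: y[X.index.get_level_values("unit") == u].iloc[0] for u in units}
    inner_folds = _stratified_unit_folds(
        list(units), [unit_label[u] for u in units], config.n_inner_folds, rng
    )

    current = list(features)
    errors: dict[int, float] = {}
    sets: dict[int, list[str]] = {}
    while True:
        k = len(current)
        sets[k] = list(current)
        fold_err = []
        importances = np.zeros(k)
        for fold in inner_folds:
            mask = X.index.get_level_values("unit").isin(fold)
            X_tr, y_tr = X.loc[~mask, current], y[~mask]
            X_va, y_va = X.loc[mask, current], y[mask]
            if y_tr.nunique() < 2 or len(y_va) == 0:
                continue
            clf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            ).fit(X_tr, y_tr)
            fold_err.append(float((clf.predict(X_va) != y_va).mean()))
            importances += _importance(clf, X_va, y_va, config.importance, rng)
        errors[k] = float(np.mean(fold_err)) if fold_err else 1.0
        if k <= config.min_variables:
            break
        keep = max(config.min_variables, int(np.floor(k * (1.0 - config.drop_fraction))))
        if keep == k:
            keep = k - 1
        order = np.argsort(-importances, kind="stable")
        current = [current[i] for i in order[:keep]]

    counts = sorted(errors)
    best_err = min(errors.values())
    optimal = [k for k in counts if errors[k] <= best_err + 1e-12]
    if config.model_choice == "min":
        k_star = min(optimal)
    elif config.model_choice == "max":
        k_star = max(optimal)
    else:
        k_star = optimal[len(optimal) // 2]
    return sets[k_star], errors


def rdcv_select(
    values: pd.DataFrame,
    labels: pd.Series,
    config: RdCvConfig = RdCvConfig(),
    patient_ids: pd.Series | None = None,
) -> SelectionResult:
    """Run rdCV random-forest variable selection.

    Parameters
    ----------
    values
        Samples × proteins feature table (complete; no missing values).
    labels
        Binary class per sample (e.g. 'fast'/'slow'), indexed like ``values``.
    patient_ids
        Optional per-sample patient assignment used for patient-stratified
        folds (all visits of a patient share a fold). Defaults to treating
        each sample as its own unit.
    """
    config.validate()
    if values.isna().any().any():
        raise ValueError("feature table contains missing values")
    labels = labels.loc[values.index]
    if labels.nunique() != 2:
        raise ValueError("exactly two classes required")
    if labels.value_counts().min() < 2:
        raise ValueError("need >= 2 samples per class")

    if patient_ids is None or not config.patient_stratified:
        units = pd.Series(values.index, index=values.index)
    else:
        units = patient_ids.loc[values.index]
    Xu = values.copy()
    Xu.index = pd.MultiIndex.from_arrays([values.index, units.values], names=["sample", "unit"])

    seedseq = np.random.SeedSequence(config.seed)
    rep_seeds = seedseq.spawn(config.n_repetitions)

    proteins = list(values.columns)
    freq = pd.Series(0.0, index=proteins)
    prob_sum = pd.Series(0.0, index=values.index, dtype=float)
    prob_n = pd.Series(0, index=values.index, dtype=int)
    per_rep_sets: list[set[str]] = []

    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        unit_list = list(pd.unique(units))
        unit_label = {u: labels[units == u].iloc[0] for u in unit_list}
        outer_folds = _stratified_unit_folds(
            unit_list, [unit_label[u] for u in unit_list], config.n_outer_folds, rng
        )
        fold_sets: list[set[str]] = []
        for fold in outer_folds:
            test_mask = units.isin(fold).values
            X_tr, y_tr = Xu.loc[~test_mask], labels[~test_mask]
            X_te, y_te = Xu.loc[test_mask], labels[test_mask]
            if y_tr.nunique() < 2:
                continue
            chosen, _ = _eliminate(X_tr, y_tr, proteins, config, rng)
            clf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            ).fit(X_tr[chosen], y_tr)
            proba = clf.predict_proba(X_te[chosen])
            class_index = {c: i for i, c in enumerate(clf.classes_)}
            own = np.array([proba[i, class_index[c]] for i, c in enumerate(y_te)])
            samp = X_te.index.get_level_values("sample")
            prob_sum.loc[samp] += own
            prob_n.loc[samp] += 1
            fold_sets.append(set(chosen))
        if fold_sets:
            counts = pd.Series(0, index=proteins)
            for s in fold_sets:
                counts[list(s)] += 1
            rep_set = set(counts.index[counts >= len(fold_sets) / 2.0])
        else:
            rep_set = set()
        per_rep_sets.append(rep_set)
        freq[list(rep_set)] += 1

    freq = freq / config.n_repetitions
    selected = sorted(
        [p for p in proteins if freq[p] >= 0.5], key=lambda p: (-freq[p], p)
    )
    with np.errstate(invalid="ignore"):
        prob = prob_sum / prob_n.replace(0, np.nan)
    misclassified = [s for s in values.index if prob_n[s] > 0 and prob[s] < 0.5]
    return SelectionResult(
        selected_proteins=selected,
        selection_frequency=freq,
        per_repetition_sets=per_rep_sets,
        per_sample_probability=prob,
        misclassified=misclassified,
        n_misclassified=len(misclassified),
        labels=labels,
    )


def swim_lane_table(result: SelectionResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-visit class probabilities with an overall per-patient call.

    One row per sample: patient, visit, mean probability of the sample's own
    class, whether the visit is misclassified (probability < 0.5), whether it
    is a high-confidence call (probability > 0.9), and the patient-level call
    (majority of visit calls, ties broken by mean probability).
    """
    meta = metadata.set_index("sample_id")
    rows = []
    for sample, p in result.per_sample_probability.items():
        if np.isnan(p):
            continue
        rows.append(
            {
                "sample_id": sample,
                "patient_id": meta.loc[sample, "patient_id"],
                "visit_index": int(meta.loc[sample, "visit_index"]),
                "prob_own_class": float(p),
                "misclassified": bool(p < 0.5),
                "high_confidence": bool(p > 0.9),
            }
        )
    table = pd.DataFrame(rows).sort_values(["patient_id", "visit_index"]).reset_index(drop=True)
    calls = {}
    for pid, grp in table.groupby("patient_id"):
        correct = (~grp["misclassified"]).sum()
        if correct * 2 != len(grp):
            calls[pid] = correct * 2 > len(grp)
        else:
            calls[pid] = bool(grp["prob_own_class"].mean() >= 0.5)
    table["patient_call_correct"] = table["patient_id"].map(calls)
    return table
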