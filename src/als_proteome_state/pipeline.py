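"""End-to-end pipeline orchestration from a single YAML-able config.

Stages run in a fixed order (synth → preprocess → differential → select →
evaluate → trajectories → mi_rank → state_transition); each draws a
deterministic sub-seed from the global seed, and a JSON manifest records
per-stage outputs, seeds and file hashes so a rerun with the same config and
seed is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import traceback
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import AbundanceMatrix
from .differential import four_way_panel, sample_groups
from .mi_ranking import rank_by_mi
from .muvr_select import RdCvConfig, rdcv_select, swim_lane_table
from .panel_eval import evaluate_panel
from .preprocess import batch_adjust, filter_proteins, impute_protein_means, vst_normalize
from .state_transition import (
    backcast,
    fit_ou,
    pc1_trajectories,
    simulate_ou,
    variance_biomarker,
)
from .synthetic_cohort import CohortSpec, generate_cohort, read_cohort, write_cohort
from .trajectories import baseline_compare, fit_random_slope_model

STAGE_ORDER = (
    "synth",
    "preprocess",
    "differential",
    "select",
    "evaluate",
    "trajectories",
    "mi_rank",
    "state_transition",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {name: True for name in STAGE_ORDER},
    "synth": {},
    "preprocess": {"max_missing_frac": 0.5},
    "differential": {"fc_threshold": 1.5, "alpha": 0.0125},
    "select": {"n_repetitions": 5, "n_trees": 64, "max_panel": 50},
    "evaluate": {"n_markers": 3, "n_boot": 1000},
    "trajectories": {"n_markers": 3},
    "mi_rank": {"k": 20},
    "state_transition": {"n_sim_paths": 200, "backcast_months": 30},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _labels(metadata: pd.DataFrame) -> pd.Series:
    groups = sample_groups(metadata)
    return groups[groups.isin(["fast", "slow"])]


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    A stage failure is recorded in the manifest and downstream stages are
    skipped.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}
    state: dict = {}
    failed = False

    for stage in STAGE_ORDER:
        if not cfg["stages"].get(stage, True):
            continue
        if failed:
            manifest["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        sseed = stage_seed(seed, stage)
        try:
            files = _STAGE_FUNCS[stage](cfg[stage], state, out, sseed)
            manifest["stages"][stage] = {
                "status": "ok",
                "seed": sseed,
                "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            }
        except Exception as exc:  # noqa: BLE001 - manifest records any failure
            manifest["stages"][stage] = {
                "status": "failed",
                "seed": sseed,
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
            failed = True

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_synth(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    spec = CohortSpec(**{**params, "seed": seed})
    matrix, metadata = generate_cohort(spec)
    d = out / "cohort"
    write_cohort(matrix, metadata, d)
    state["matrix"], state["metadata"] = matrix, metadata
    return [d / "abundance.tsv", d / "metadata.tsv"]


def _stage_preprocess(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    if "matrix" not in state:
        state["matrix"], state["metadata"] = read_cohort(out / "cohort")
    m = vst_normalize(state["matrix"])
    m = batch_adjust(m, state["metadata"])
    m = filter_proteins(m, params["max_missing_frac"])
    d = out / "preprocessed"
    write_cohort(m, state["metadata"], d)
    state["matrix"] = m
    return [d / "abundance.tsv", d / "metadata.tsv"]


def _stage_differential(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    panel, results = four_way_panel(
        state["matrix"],
        state["metadata"],
        fc_threshold=params["fc_threshold"],
        alpha=params["alpha"],
    )
    d = out / "differential"
    d.mkdir(exist_ok=True)
    files = []
    for name, res in results.items():
        f = d / f"{name}.tsv"
        res.to_csv(f, sep="\t", index=False)
        files.append(f)
    f = d / "panel.txt"
    f.write_text("\n".join(panel) + ("\n" if panel else ""))
    files.append(f)
    state["panel"] = panel
    return files


def _panel_features(state: dict, max_panel: int) -> pd.DataFrame:
    """Complete samples × proteins table for the candidate panel (falls back
    to the most variable proteins when the differential panel is empty)."""
    matrix: AbundanceMatrix = state["matrix"]
    panel = state.get("panel") or []
    if not panel:
        panel = (
            matrix.values.var(axis=1, skipna=True).nlargest(max_panel).index.tolist()
        )
    panel = panel[:max_panel]
    complete = impute_protein_means(matrix.subset_proteins(panel))
    labels = _labels(state["metadata"])
    return complete.values.T.loc[labels.index], labels


def _stage_select(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    features, labels = _panel_features(state, params["max_panel"])
    meta = state["metadata"].set_index("sample_id")
    patient_ids = meta.loc[features.index, "patient_id"]
    config = RdCvConfig(
        n_repetitions=params["n_repetitions"], n_trees=params["n_trees"], seed=seed
    )
    result = rdcv_select(features, labels, config, patient_ids=patient_ids)
    state["selection"] = result
    d = out / "selection"
    d.mkdir(exist_ok=True)
    f1 = d / "selection.json"
    f1.write_text(
        json.dumps(
            {
                "selected_proteins": result.selected_proteins,
                "selection_frequency": result.selection_frequency.round(4).to_dict(),
                "n_misclassified": result.n_misclassified,
                "misclassified": result.misclassified,
            },
            indent=2,
        )
    )
    f2 = d / "swim_lanes.tsv"
    swim_lane_table(result, state["metadata"]).to_csv(f2, sep="\t", index=False)
    return [f1, f2]


def _top_markers(state: dict, n: int) -> list[str]:
    sel = state.get("selection")
    if sel is not None and sel.selected_proteins:
        return sel.selected_proteins[:n]
    return (state.get("panel") or state["matrix"].protein_ids)[:n]


def _stage_evaluate(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    markers = _top_markers(state, params["n_markers"])
    labels = _labels(state["metadata"])
    sub = impute_protein_means(state["matrix"].subset_proteins(markers))
    X = sub.values.T.loc[labels.index].to_numpy()
    y = (labels == "fast").astype(int).to_numpy()
    report = {}
    for name, Xi in [("panel", X)] + [(m, X[:, [i]]) for i, m in enumerate(markers)]:
        r = evaluate_panel(Xi, y, n_boot=params["n_boot"], seed=np.random.default_rng(seed))
        report[name] = {
            "auc": round(r.auc, 4),
            "ci_low": round(r.ci_low, 4),
            "ci_high": round(r.ci_high, 4),
            "criterion": round(r.criterion, 4),
            "sensitivity": round(r.sensitivity, 4),
            "specificity": round(r.specificity, 4),
        }
    d = out / "evaluation"
    d.mkdir(exist_ok=True)
    f = d / "roc.json"
    f.write_text(json.dumps({"markers": markers, "results": report}, indent=2))
    return [f]


def _stage_trajectories(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    markers = _top_markers(state, params["n_markers"])
    meta = state["metadata"]
    labels = _labels(meta)
    meta_fs = meta[meta["sample_id"].isin(labels.index)]
    sub = impute_protein_means(state["matrix"].subset_proteins(markers))
    report = {}
    for m in markers:
        vals = sub.values.loc[m, meta_fs["sample_id"]].to_numpy()
        fit = fit_random_slope_model(
            vals,
            meta_fs["months_from_baseline"].to_numpy(float),
            meta_fs["patient_id"].to_numpy(),
            labels.loc[meta_fs["sample_id"]].to_numpy(),
            meta_fs["age_at_onset"].fillna(meta_fs["age_at_onset"].mean()).to_numpy(float),
        )
        base = meta_fs[meta_fs["visit_index"] == 0]
        p_base = baseline_compare(
            sub.values.loc[m, base["sample_id"]].to_numpy(),
            labels.loc[base["sample_id"]].to_numpy(),
        )
        report[m] = {
            "slopes": {g: round(v, 5) for g, v in fit.fixed_slope.items()},
            "slope_p": {g: round(v, 5) for g, v in fit.slope_p_value.items()},
            "baseline_mw_p": round(p_base, 5),
            "converged": fit.converged,
        }
    d = out / "trajectories"
    d.mkdir(exist_ok=True)
    f = d / "lmm.json"
    f.write_text(json.dumps(report, indent=2))
    return [f]


def _stage_mi_rank(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    labels = _labels(state["metadata"])
    matrix = state["matrix"].subset_samples(list(labels.index))
    ranking = rank_by_mi(matrix, labels, k=min(params["k"], matrix.n_proteins), seed=seed)
    d = out / "mi"
    d.mkdir(exist_ok=True)
    f = d / "mi.tsv"
    ranking.as_frame().to_csv(f, sep="\t", index=False)
    return [f]


def _stage_state_transition(params: dict, state: dict, out: Path, seed: int) -> list[Path]:
    labels = _labels(state["metadata"])
    matrix = impute_protein_means(state["matrix"].subset_samples(list(labels.index)))
    meta = state["metadata"]
    traj = pc1_trajectories(matrix, meta[meta["sample_id"].isin(labels.index)])
    fits = fit_ou(traj)
    var_stat = variance_biomarker(traj)
    rng = np.random.default_rng(seed)
    d = out / "state_transition"
    d.mkdir(exist_ok=True)
    rows = []
    t_grid = np.linspace(0.0, 30.0, 121)
    for group, fit in fits.items():
        paths = simulate_ou(fit.params, t_grid, params["n_sim_paths"], rng)
        for i in range(min(paths.shape[0], 20)):  # keep the export small
            for t, v in zip(t_grid, paths[i]):
                rows.append((group, f"{group}_{i}", round(t, 3), round(float(v), 5)))
        tb, back = backcast(
            fit.params,
            x_at_zero=fit.params.x0,
            t_back_months=params["backcast_months"],
            n_paths=params["n_sim_paths"],
            seed=rng,
        )
        for i in range(min(back.shape[0], 20)):
            for t, v in zip(tb, back[i]):
                rows.append((group, f"{group}_back_{i}", round(float(t), 3), round(float(v), 5)))
    f1 = d / "paths.tsv"
    pd.DataFrame(rows, columns=["group", "path_id", "time", "value"]).to_csv(
        f1, sep="\t", index=False
    )
    f2 = d / "ou.json"
    f2.write_text(
        json.dumps(
            {
                "fits": {
                    g: {
                        "theta": round(fit.params.theta, 6),
                        "mu": round(fit.params.mu, 6),
                        "beta_inv": round(fit.params.beta_inv, 6),
                        "stationary_variance": round(fit.params.stationary_variance, 6),
                        "converged": fit.converged,
                        "loglik": round(fit.loglik, 4),
                    }
                    for g, fit in fits.items()
                },
                "variance_biomarker": {
                    "per_group_median": {
                        g: round(v, 6) for g, v in var_stat["per_group_median"].items()
                    },
                    "fast_slow_ratio": round(var_stat.get("fast_slow_ratio", float("nan")), 6),
                },
            },
            indent=2,
        )
    )
    return [f1, f2]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "differential": _stage_differential,
    "select": _stage_select,
    "evaluate": _stage_evaluate,
    "trajectories": _stage_trajectories,
    "mi_rank": _stage_mi_rank,
    "state_transition": _stage_state_transition,
}
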