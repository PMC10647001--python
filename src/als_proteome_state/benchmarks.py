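"""Reference computations exercising each analysis stage on known ground truth.

These are the quantities the package can verify without the raw
mass-spectrometry deposit: the cohort-table demographics (recomputable from
the published patient-level table alone) and simulation studies in which the
generator's truth is known — OU stationary behavior, OU parameter-ordering
recovery, planted-signal recovery of the differential panel and of rdCV
selection, and the calibration of the MI estimator.

Every function is deterministic given its seed and returns plain dicts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import demographics
from .differential import four_way_panel, progression_label
from .mi_ranking import label_entropy, mutual_information_cd
from .muvr_select import RdCvConfig, rdcv_select
from .panel_eval import exact_mann_whitney, fisher_exact_2x2
from .preprocess import impute_protein_means
from .state_transition import OUParams, TrajectorySet, fit_ou, simulate_ou
from .synthetic_cohort import CohortSpec, generate_cohort, signal_protein_ids


# ---------------------------------------------------------------------------
# Cohort-table demographics


def cohort_label_counts(cohort: pd.DataFrame) -> dict[str, int]:
    """Progression-group counts from a demographics table's ALSFRS-R slopes."""
    labels = cohort["alsfrsr_slope"].map(progression_label)
    return {
        "fast": int((labels == "fast").sum()),
        "slow": int((labels == "slow").sum()),
        "intermediate": int((labels == "intermediate").sum()),
    }


def discovery_sex_fisher_p() -> float:
    """Two-sided Fisher exact p for sex vs progression group (discovery)."""
    d = demographics.discovery_cohort()
    grp = d["alsfrsr_slope"].map(progression_label)
    table = [
        [int(((grp == g) & (d["sex"] == s)).sum()) for s in ("M", "F")]
        for g in ("fast", "slow")
    ]
    return fisher_exact_2x2(table)


def discovery_age_onset_mw_p() -> float:
    """Exact two-sided Mann-Whitney p for age at onset vs group (discovery)."""
    d = demographics.discovery_cohort()
    grp = d["alsfrsr_slope"].map(progression_label)
    ages = d["age_at_onset"].astype(float)
    return exact_mann_whitney(ages[grp == "slow"], ages[grp == "fast"])


# ---------------------------------------------------------------------------
# OU process correctness


def ou_stationary_check(
    seed: int = 0,
    theta: float = 0.5,
    beta_inv: float = 2.0,
    n_paths: int = 2000,
    lag: float = 1.0,
) -> dict:
    """Simulated stationary variance and lag autocorrelation vs closed forms.

    Paths start at mu and run long enough (T = 40/theta) for the marginal to
    converge; variance is read at the final time, autocorrelation between the
    final time and final time minus ``lag``.
    """
    params = OUParams(theta=theta, mu=1.0, beta_inv=beta_inv, x0=1.0)
    horizon = 40.0 / theta
    t = np.arange(0.0, horizon + lag / 2, lag / 2)
    paths = simulate_ou(params, t, n_paths, seed)
    x_end = paths[:, -1]
    x_lag = paths[:, -1 - int(round(lag / (lag / 2)))]
    var_obs = float(np.var(x_end, ddof=1))
    var_exp = params.stationary_variance
    var_se = var_exp * np.sqrt(2.0 / (n_paths - 1))
    rho_obs = float(np.corrcoef(x_end, x_lag)[0, 1])
    rho_exp = float(np.exp(-theta * lag))
    rho_se = (1.0 - rho_exp**2) / np.sqrt(n_paths)
    return {
        "stationary_variance": var_obs,
        "stationary_variance_expected": var_exp,
        "stationary_variance_3se": 3.0 * var_se,
        "autocorrelation": rho_obs,
        "autocorrelation_expected": rho_exp,
        "autocorrelation_3se": 3.0 * rho_se,
        "n_paths": n_paths,
    }


def _simulate_group(params: OUParams, n_patients, times, rng, group):
    rows = []
    sd0 = np.sqrt(params.stationary_variance)
    for i in range(n_patients):
        x0 = params.mu + sd0 * rng.standard_normal()
        p = OUParams(params.theta, params.mu, params.beta_inv, x0=float(x0))
        path = simulate_ou(p, times, 1, rng)[0]
        for t, x in zip(times, path):
            rows.append((f"{group}{i}", float(t), float(x), group))
    return rows


def ou_ordering_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    n_patients: int = 10,
    n_visits: int = 8,
    spacing: float = 3.0,
) -> dict:
    """Fraction of replicates in which joint MLE recovers both parameter
    orderings (theta and beta_inv larger in the fast group).

    Truth: slow (theta=0.08/month, beta_inv=0.3), fast (theta=0.4,
    beta_inv=1.5), shared mu=0.
    """
    slow = OUParams(theta=0.08, mu=0.0, beta_inv=0.3)
    fast = OUParams(theta=0.4, mu=0.0, beta_inv=1.5)
    times = np.arange(n_visits) * spacing
    rng = np.random.default_rng(seed)
    hits_theta = hits_beta = hits_both = 0
    for _ in range(n_replicates):
        rows = _simulate_group(fast, n_patients, times, rng, "fast") + _simulate_group(
            slow, n_patients, times, rng, "slow"
        )
        traj = TrajectorySet(pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"]))
        fits = fit_ou(traj)
        ok_t = fits["slow"].params.theta < fits["fast"].params.theta
        ok_b = fits["slow"].params.beta_inv < fits["fast"].params.beta_inv
        hits_theta += ok_t
        hits_beta += ok_b
        hits_both += ok_t and ok_b
    return {
        "theta_ordering_rate": hits_theta / n_replicates,
        "beta_inv_ordering_rate": hits_beta / n_replicates,
        "both_orderings_rate": hits_both / n_replicates,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Differential four-way panel recovery


def _recovery_spec(seed: int, **overrides) -> CohortSpec:
    base = dict(
        n_fast=20,
        n_slow=20,
        visits_per_patient=(3, 3),
        n_proteins=1150,
        n_signal_proteins=50,
        group_effect_log2=2.0,
        within_patient_sd_fast=0.4,
        within_patient_sd_slow=0.3,
        patient_random_effect_sd=0.3,
        batch_count=1,
        batch_effect_sd=0.0,
        missing_rate=0.1,
        missing_mnar_weight=0.5,
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


def four_way_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Sensitivity and false-discovery proportion of the four-way panel on
    cohorts with 50 planted signal proteins (|log2FC| = 2) among 1100 nulls.

    The study-sized cohort (6 vs 5 patients) is too small for a BH-adjusted
    p <= 0.0125 rule under an exact rank test (minimum attainable p is
    2/462), so the recovery study uses 20 patients per group.
    """
    sens, fdp = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        spec = _recovery_spec(int(rng.integers(2**31)))
        matrix, metadata = generate_cohort(spec)
        panel, _ = four_way_panel(matrix, metadata)
        truth = set(signal_protein_ids(spec))
        found = set(panel)
        sens.append(len(found & truth) / len(truth))
        fdp.append(len(found - truth) / max(len(found), 1))
    return {
        "median_sensitivity": float(np.median(sens)),
        "median_fdp": float(np.median(fdp)),
        "n_seeds": n_seeds,
        "n_patients_per_group": 20,
    }


def four_way_null(seed: int = 0) -> dict:
    """Panel size on a cohort with no group effect (should be empty)."""
    spec = _recovery_spec(seed, n_signal_proteins=0, n_proteins=400)
    matrix, metadata = generate_cohort(spec)
    panel, _ = four_way_panel(matrix, metadata)
    return {"panel_size": len(panel)}


# ---------------------------------------------------------------------------
# rdCV selection recovery


def _rdcv_cohort(seed: int) -> tuple[pd.DataFrame, pd.Series, pd.Series, CohortSpec]:
    spec = CohortSpec(
        n_fast=6,
        n_slow=5,
        visits_per_patient=(4, 4),
        n_proteins=303,
        n_signal_proteins=3,
        group_effect_log2=2.0,
        within_patient_sd_fast=0.4,
        within_patient_sd_slow=0.3,
        patient_random_effect_sd=0.3,
        batch_count=1,
        batch_effect_sd=0.0,
        missing_rate=0.0,
        seed=seed,
    )
    matrix, metadata = generate_cohort(spec)
    from .differential import sample_groups

    labels = sample_groups(metadata)
    features = impute_protein_means(matrix).values.T.loc[labels.index]
    patients = metadata.set_index("sample_id").loc[labels.index, "patient_id"]
    return features, labels, patients, spec


#: Scaled rdCV configuration used by the recovery studies. The mid model is
#: used because the question here is all-relevant recovery: the min model is
#: deliberately parsimonious and, when two of three redundant markers already
#: achieve zero inner error, correctly returns the smaller subset.
RECOVERY_RDCV = dict(
    n_outer_folds=5, n_inner_folds=4, drop_fraction=0.3, n_trees=32, model_choice="mid"
)


def rdcv_recovery(seed: int = 0, n_repetitions: int = 8) -> dict:
    """Fraction of rdCV repetitions selecting all 3 planted markers among
    300 nulls, plus overall misclassification."""
    features, labels, patients, spec = _rdcv_cohort(seed)
    config = RdCvConfig(n_repetitions=n_repetitions, seed=seed + 1, **RECOVERY_RDCV)
    result = rdcv_select(features, labels, config, patient_ids=patients)
    truth = set(signal_protein_ids(spec))
    hit = sum(truth <= s for s in result.per_repetition_sets)
    return {
        "all_signals_selected_rate": hit / n_repetitions,
        "n_repetitions": n_repetitions,
        "misclassification_rate": result.n_misclassified
        / int(result.per_sample_probability.notna().sum()),
        "selected_proteins": result.selected_proteins,
    }


def rdcv_permuted(seed: int = 0, n_repetitions: int = 4) -> dict:
    """Misclassification under patient-level label permutation (~50%)."""
    features, labels, patients, _ = _rdcv_cohort(seed)
    rng = np.random.default_rng(seed + 17)
    unique_patients = list(pd.unique(patients))
    patient_label = {p: labels[patients == p].iloc[0] for p in unique_patients}
    shuffled = list(patient_label.values())
    rng.shuffle(shuffled)
    permuted_map = dict(zip(unique_patients, shuffled))
    permuted = patients.map(permuted_map)
    config = RdCvConfig(n_repetitions=n_repetitions, seed=seed + 2, **RECOVERY_RDCV)
    result = rdcv_select(features, permuted, config, patient_ids=patients)
    n_pred = int(result.per_sample_probability.notna().sum())
    return {
        "misclassification_rate": result.n_misclassified / n_pred,
        "n_samples": n_pred,
    }


# ---------------------------------------------------------------------------
# MI estimator calibration


def mi_estimator_checks(seed: int = 0, n_sims: int = 200, n_samples: int = 200) -> dict:
    """Null mean, perfect-separation limit and entropy bound of the MI
    estimator on balanced two-class data."""
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n_samples // 2) + [1] * (n_samples - n_samples // 2))
    h = label_entropy(y)
    null_mis = []
    max_mi = 0.0
    for i in range(n_sims):
        x = rng.standard_normal(n_samples)
        mi = mutual_information_cd(x, y, seed=int(rng.integers(2**31)))
        null_mis.append(mi)
        max_mi = max(max_mi, mi)
    x_sep = y + rng.normal(0.0, 1e-6, size=n_samples)
    mi_sep = mutual_information_cd(x_sep, y, seed=seed)
    return {
        "null_mean_mi": float(np.mean(null_mis)),
        "perfect_separation_mi": float(mi_sep),
        "label_entropy": float(h),
        "max_null_mi": float(max_mi),
        "n_sims": n_sims,
    }
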