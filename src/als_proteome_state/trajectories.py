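"""Longitudinal modeling of candidate markers.

Baseline group differences use the exact Mann-Whitney test; temporal behavior
is modeled with a random-slope, random-intercept linear mixed model with age
at first draw as a covariate:

    value ~ group + group:months + age + (1 + months | patient)

fitted by maximum likelihood. The group-specific slope significance is a
likelihood-ratio test of that slope against zero, which matches the question
the trajectory panels ask: does the marker drift over time within a group?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranktests import exact_mann_whitney


@dataclass
class LmmFit:
    fixed_intercept: float
    fixed_slope: dict  # group -> slope (units/month)
    age_covariate_coef: float
    slope_p_value: dict  # group -> LRT p-value for slope == 0
    random_intercept_var: float
    random_slope_var: float
    residual_var: float
    converged: bool
    loglik: float = float("nan")
    diagonal_fallback: bool = False


def _design(times, group_labels, age, groups):
    """Columns: intercept, indicator per non-reference group, one slope per
    group, centered age."""
    n = len(times)
    cols = [np.ones(n)]
    names = ["intercept"]
    for g in groups[1:]:
        cols.append((group_labels == g).astype(float))
        names.append(f"group[{g}]")
    for g in groups:
        cols.append(np.where(group_labels == g, times, 0.0))
        names.append(f"slope[{g}]")
    cols.append(age - np.mean(age))
    names.append("age")
    return np.column_stack(cols), names


def _fit_mixedlm(y, X, names, patients, times, re_slope=True):
    import statsmodels.api as sm

    exog_re = np.column_stack([np.ones(len(y)), times]) if re_slope else np.ones((len(y), 1))
    model = sm.MixedLM(y, X, groups=patients, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method=["lbfgs", "powell"], maxiter=500)
    return fit


def fit_random_slope_model(
    values,
    times,
    patient_ids,
    group_labels,
    age_at_first_draw,
) -> LmmFit:
    """ML fit of the random-slope model with per-group LRT slope tests.

    All arguments are per-sample arrays of equal length; ``times`` is months
    from baseline. If the full random-effects covariance cannot be estimated,
    the model falls back to a random intercept only and flags it.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    pid = np.asarray(patient_ids)
    grp = np.asarray(group_labels)
    age = np.asarray(age_at_first_draw, dtype=float)
    groups = sorted(pd.unique(grp))

    for g in groups:
        if len(np.unique(pid[grp == g])) < 3:
            warnings.warn(f"group {g!r} has < 3 patients; mixed-model fit may be unstable",
                          stacklevel=2)

    if np.ptp(y) == 0:
        return LmmFit(
            fixed_intercept=float(y[0]),
            fixed_slope={g: 0.0 for g in groups},
            age_covariate_coef=0.0,
            slope_p_value={g: 1.0 for g in groups},
            random_intercept_var=0.0,
            random_slope_var=0.0,
            residual_var=0.0,
            converged=True,
        )

    X, names = _design(t, grp, age, groups)
    diagonal_fallback = False
    try:
        fit = _fit_mixedlm(y, X, names, pid, t, re_slope=True)
        cov = np.atleast_2d(fit.cov_re)
        if not np.all(np.linalg.eigvalsh(cov) > -1e-10):
            raise ValueError("non-PSD random-effects covariance")
    except Exception:
        diagonal_fallback = True
        fit = _fit_mixedlm(y, X, names, pid, t, re_slope=False)

    params = dict(zip(names, np.asarray(fit.fe_params)))
    ll_full = float(fit.llf)

    slope_p: dict = {}
    for g in groups:
        drop = names.index(f"slope[{g}]")
        Xr = np.delete(X, drop, axis=1)
        nr = [n for i, n in enumerate(names) if i != drop]
        try:
            fit_r = _fit_mixedlm(y, Xr, nr, pid, t, re_slope=not diagonal_fallback)
            lr = max(0.0, 2.0 * (ll_full - float(fit_r.llf)))
            slope_p[g] = float(stats.chi2.sf(lr, df=1))
        except Exception:
            slope_p[g] = float("nan")

    cov = np.atleast_2d(fit.cov_re)
    ri_var = float(cov[0, 0])
    rs_var = float(cov[1, 1]) if cov.shape[0] > 1 else 0.0
    return LmmFit(
        fixed_intercept=float(params["intercept"]),
        fixed_slope={g: float(params[f"slope[{g}]"]) for g in groups},
        age_covariate_coef=float(params["age"]),
        slope_p_value=slope_p,
        random_intercept_var=ri_var,
        random_slope_var=rs_var,
        residual_var=float(fit.scale),
        converged=bool(getattr(fit, "converged", True)),
        loglik=ll_full,
        diagonal_fallback=diagonal_fallback,
    )


def baseline_compare(first_visit_values, group_labels) -> float:
    """Two-sided exact Mann-Whitney p comparing baseline marker levels
    between the two progression groups."""
    v = np.asarray(first_visit_values, dtype=float)
    g = np.asarray(group_labels)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    return exact_mann_whitney(v[g == labels[0]], v[g == labels[1]])
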