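"""Ornstein-Uhlenbeck state-transition model of the CSF proteome.

The scalar proteome state X_t (the first principal component of the
protein × sample matrix) is modeled as a mean-reverting diffusion

    dX_t = theta * (mu - X_t) dt + sqrt(2 / beta) dB_t

where theta (1/month) sets the timescale of progression toward the attractor
state mu ("state of ALS"), and beta_inv = 1/beta scales the stochastic
fluctuation — the proteome entropy. The stationary variance is beta_inv /
theta and the lag-D autocorrelation is exp(-theta * D). Fast progressors are
characterised by larger theta and larger beta_inv than slow progressors.

Everything here uses the exact Gaussian transition density

    X_{t+D} | X_t ~ N(mu + (X_t - mu) e^{-theta D},
                      (beta_inv / theta) (1 - e^{-2 theta D}))

for simulation, likelihood and bridge sampling, so there is no
discretization bias at any step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import AbundanceMatrix
from .differential import sample_groups
from .panel_eval import pca_project


@dataclass(frozen=True)
class OUParams:
    theta: float  # mean-reversion rate, 1/month
    mu: float  # attractor state, PC1 units
    beta_inv: float  # fluctuation variance scale
    x0: float = 0.0  # initial state for simulation

    def validate(self, allow_zero_noise: bool = False) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if self.beta_inv < 0 or (self.beta_inv == 0 and not allow_zero_noise):
            raise ValueError("beta_inv must be positive")

    @property
    def stationary_variance(self) -> float:
        return self.beta_inv / self.theta


@dataclass
class TrajectorySet:
    """Per-patient time series of the scalar proteome state."""

    data: pd.DataFrame  # columns: patient_id, months, state, group

    def __post_init__(self) -> None:
        for pid, grp in self.data.groupby("patient_id"):
            t = grp["months"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"patient {pid}: times not strictly increasing")

    def patients(self, group: str | None = None) -> list:
        d = self.data if group is None else self.data[self.data["group"] == group]
        return list(pd.unique(d["patient_id"]))

    def series(self, patient_id) -> tuple[np.ndarray, np.ndarray]:
        grp = self.data[self.data["patient_id"] == patient_id]
        return grp["months"].to_numpy(float), grp["state"].to_numpy(float)

    def groups(self) -> list:
        return sorted(pd.unique(self.data["group"]))


def pc1_trajectories(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> TrajectorySet:
    """Project every sample onto PC1 and assemble per-patient trajectories.

    The matrix must be complete (impute upstream and flag it). PC1 sign is
    fixed so the fast-progressor group mean is >= the slow-progressor mean.
    """
    scores, _ = pca_project(matrix, n_components=1)
    pc1 = scores["PC1"]
    groups = sample_groups(metadata)
    fast_mean = pc1[groups.loc[pc1.index] == "fast"].mean()
    slow_mean = pc1[groups.loc[pc1.index] == "slow"].mean()
    if np.isfinite(fast_mean) and np.isfinite(slow_mean) and fast_mean < slow_mean:
        pc1 = -pc1
    meta = metadata.set_index("sample_id")
    data = pd.DataFrame(
        {
            "patient_id": meta.loc[pc1.index, "patient_id"].to_numpy(),
            "months": meta.loc[pc1.index, "months_from_baseline"].to_numpy(float),
            "state": pc1.to_numpy(),
            "group": groups.loc[pc1.index].to_numpy(),
        }
    ).sort_values(["patient_id", "months"]).reset_index(drop=True)
    return TrajectorySet(data=data)


def _transition_moments(params: OUParams, x, dt):
    """Exact conditional mean and variance of X_{t+dt} given X_t = x."""
    e = np.exp(-params.theta * np.asarray(dt, dtype=float))
    mean = params.mu + (np.asarray(x, dtype=float) - params.mu) * e
    var = (params.beta_inv / params.theta) * (1.0 - e**2)
    return mean, var


def simulate_ou(
    params: OUParams,
    t_grid,
    n_paths: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample OU paths on t_grid by exact transition sampling.

    Returns an (n_paths, len(t_grid)) array; every path starts at params.x0
    at t_grid[0]. Deterministic under a fixed seed.
    """
    params.validate(allow_zero_noise=True)
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1 or not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be increasing")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    paths = np.empty((n_paths, len(t)))
    paths[:, 0] = params.x0
    for j in range(1, len(t)):
        mean, var = _transition_moments(params, paths[:, j - 1], t[j] - t[j - 1])
        paths[:, j] = mean + np.sqrt(var) * rng.standard_normal(n_paths)
    return paths


def ou_loglik(
    params: OUParams,
    times,
    states,
    condition_on_first: bool = True,
) -> float:
    """Exact log-likelihood of one observed trajectory under OU dynamics.

    Sums the Gaussian transition log-densities over consecutive pairs. By
    default the first observation is conditioned on (the first CSF draw is
    not the start of the process); otherwise its stationary density is added.
    """
    params.validate()
    t = np.asarray(times, dtype=float)
    x = np.asarray(states, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or decreasing times")
    mean, var = _transition_moments(params, x[:-1], np.diff(t))
    ll = float(np.sum(-0.5 * (np.log(2 * np.pi * var) + (x[1:] - mean) ** 2 / var)))
    if not condition_on_first:
        sv = params.stationary_variance
        ll += float(-0.5 * (np.log(2 * np.pi * sv) + (x[0] - params.mu) ** 2 / sv))
    return ll


@dataclass
class OUFit:
    params: OUParams
    converged: bool
    loglik: float
    n_transitions: int


def _group_negloglik(log_theta, mu, log_beta_inv, series):
    p = OUParams(theta=float(np.exp(log_theta)), mu=float(mu),
                 beta_inv=float(np.exp(log_beta_inv)))
    return -sum(ou_loglik(p, t, x) for t, x in series)


def fit_ou(
    trajectories: TrajectorySet,
    shared_mu: float | None = None,
) -> dict[str, OUFit]:
    """Joint MLE of (theta, mu, beta_inv) per progression group.

    All patients of a group share parameters; each patient path is
    conditioned on its first observation. Positivity of theta and beta_inv is
    enforced via log-parameterization. When ``shared_mu`` is given, mu is
    held fixed at that value (one attractor state for both groups).
    """
    fits: dict[str, OUFit] = {}
    for group in trajectories.groups():
        pats = trajectories.patients(group)
        series = []
        for pid in pats:
            t, x = trajectories.series(pid)
            if len(t) >= 2:
                series.append((t, x))
        if len(series) < 2:
            raise ValueError(f"group {group!r}: need >= 2 patients with >= 2 visits")

        all_x = np.concatenate([x for _, x in series])
        increments = np.concatenate([np.diff(x) / np.sqrt(np.diff(t)) for t, x in series])
        var0 = max(float(np.var(increments)) / 2.0, 1e-8)
        mu0 = shared_mu if shared_mu is not None else float(np.mean(all_x))
        x0_init = [np.log(0.1), np.log(var0 * 0.1)]

        degenerate = float(np.var(all_x)) < 1e-14
        if degenerate:
            warnings.warn(f"group {group!r}: constant trajectories; beta_inv at boundary",
                          stacklevel=2)
            fits[group] = OUFit(
                params=OUParams(theta=1e-8, mu=float(all_x[0]), beta_inv=0.0,
                                x0=float(all_x[0])),
                converged=False,
                loglik=float("nan"),
                n_transitions=sum(len(t) - 1 for t, _ in series),
            )
            continue

        if shared_mu is None:
            def nll(v):
                return _group_negloglik(v[0], v[1], v[2], series)
            v0 = [x0_init[0], mu0, x0_init[1]]
        else:
            def nll(v):
                return _group_negloglik(v[0], shared_mu, v[1], series)
            v0 = x0_init

        best = None
        for theta_init in (0.02, 0.1, 0.5):
            v_start = list(v0)
            v_start[0] = np.log(theta_init)
            res = optimize.minimize(nll, v_start, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        res = best
        if shared_mu is None:
            theta, mu, beta_inv = np.exp(res.x[0]), res.x[1], np.exp(res.x[2])
        else:
            theta, mu, beta_inv = np.exp(res.x[0]), shared_mu, np.exp(res.x[1])
        x0_mean = float(np.mean([x[0] for _, x in series]))
        fits[group] = OUFit(
            params=OUParams(theta=float(theta), mu=float(mu),
                            beta_inv=float(beta_inv), x0=x0_mean),
            converged=bool(res.success),
            loglik=float(-res.fun),
            n_transitions=sum(len(t) - 1 for t, _ in series),
        )
    return fits


def backcast(
    params: OUParams,
    x_at_zero: float,
    t_back_months: float,
    n_paths: int,
    seed: int | np.random.Generator = 0,
    n_steps: int = 60,
    bridge: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate presymptomatic paths on the negative time axis [-t_back, 0].

    In bridge mode (default) paths start at the presymptomatic reference
    state x = 0 at -t_back and are conditioned to end at ``x_at_zero`` at
    time 0 via sequential sampling of the exact OU diffusion bridge. With
    ``bridge=False`` paths run forward unconditioned from the reference
    state. Returns (times, paths) with paths shaped (n_paths, n_steps + 1).
    """
    params.validate(allow_zero_noise=True)
    if t_back_months <= 0:
        raise ValueError("t_back_months must be positive")
    t = np.linspace(-t_back_months, 0.0, n_steps + 1)
    start = OUParams(params.theta, params.mu, params.beta_inv, x0=0.0)
    if not bridge:
        return t, simulate_ou(start, t, n_paths, seed)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta, mu, beta_inv = params.theta, params.mu, params.beta_inv
    b = float(x_at_zero)

    def u(dt):  # variance / beta_inv
        return (1.0 - np.exp(-2.0 * theta * dt)) / theta

    paths = np.empty((n_paths, len(t)))
    paths[:, 0] = 0.0
    for j in range(1, len(t)):
        dt = t[j] - t[j - 1]
        rem = 0.0 - t[j]  # time remaining to the endpoint
        m1 = mu + (paths[:, j - 1] - mu) * np.exp(-theta * dt)
        u1 = u(dt)
        if rem <= 1e-12:
            paths[:, j] = b
            continue
        c = np.exp(-theta * rem)
        u2 = u(rem)
        denom = u2 + c**2 * u1
        mean = (m1 * u2 + c * (b - mu * (1.0 - c)) * u1) / denom
        var = beta_inv * u1 * u2 / denom
        paths[:, j] = mean + np.sqrt(var) * rng.standard_normal(n_paths)
    return t, paths


def downsample_paths(paths: np.ndarray, t_grid, visit_times) -> np.ndarray:
    """Restrict simulated paths to clinic-visit times (no re-simulation).

    Visit times on the grid are taken exactly; off-grid times are linearly
    interpolated.
    """
    t = np.asarray(t_grid, dtype=float)
    v = np.asarray(visit_times, dtype=float)
    if v.min() < t.min() - 1e-9 or v.max() > t.max() + 1e-9:
        raise ValueError("visit_times outside the simulation grid")
    out = np.empty((paths.shape[0], len(v)))
    for i in range(paths.shape[0]):
        out[i] = np.interp(v, t, paths[i])
    return out


def variance_biomarker(trajectories: TrajectorySet) -> dict:
    """Per-group proteome-variance statistic and the fast/slow ratio.

    For each patient, the mean squared PC1 increment per month (a diffusion-
    rate estimate); per group, the median across patients. Patients with a
    single visit are excluded with a warning.
    """
    per_group: dict[str, list[float]] = {}
    for group in trajectories.groups():
        stats_ = []
        for pid in trajectories.patients(group):
            t, x = trajectories.series(pid)
            if len(t) < 2:
                warnings.warn(f"patient {pid} has a single visit; excluded", stacklevel=2)
                continue
            stats_.append(float(np.mean(np.diff(x) ** 2 / np.diff(t))))
        per_group[group] = stats_
    result = {g: float(np.median(v)) if v else float("nan") for g, v in per_group.items()}
    out = {"per_group_median": result, "per_patient": per_group}
    if "fast" in result and "slow" in result and result["slow"] > 0:
        out["fast_slow_ratio"] = result["fast"] / result["slow"]
    return out
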