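import numpy as np
import pandas as pd
import pytest

from als_proteome_state.differential import sample_groups
from als_proteome_state.preprocess import impute_protein_means
from als_proteome_state.state_transition import (
    OUParams,
    TrajectorySet,
    backcast,
    downsample_paths,
    fit_ou,
    ou_loglik,
    pc1_trajectories,
    simulate_ou,
    variance_biomarker,
)


def _traj_from_paths(paths, times, group):
    rows = []
    for i, path in enumerate(paths):
        for t, x in zip(times, path):
            rows.append((f"{group}{i}", float(t), float(x), group))
    return rows


class TestSimulateOu:
    def test_noise_free_relaxation(self):
        p = OUParams(theta=0.3, mu=5.0, beta_inv=0.0, x0=1.0)
        t = np.linspace(0, 20, 11)
        paths = simulate_ou(p, t, 3, seed=0)
        expected = 5.0 + (1.0 - 5.0) * np.exp(-0.3 * t)
        assert np.allclose(paths, expected[None, :])

    def test_stationary_variance_closed_form(self):
        p = OUParams(theta=0.5, mu=0.0, beta_inv=2.0, x0=0.0)
        t = np.arange(0, 40.5, 0.5)
        paths = simulate_ou(p, t, 2000, seed=1)
        v = np.var(paths[:, -1], ddof=1)
        se = 4.0 * np.sqrt(2 / 1999)
        assert abs(v - 4.0) < 3 * se

    def test_autocorrelation_closed_form(self):
        p = OUParams(theta=0.5, mu=0.0, beta_inv=2.0, x0=0.0)
        t = np.arange(0, 41.0, 1.0)
        paths = simulate_ou(p, t, 2000, seed=2)
        rho = np.corrcoef(paths[:, -1], paths[:, -2])[0, 1]
        expected = np.exp(-0.5)
        se = (1 - expected**2) / np.sqrt(2000)
        assert abs(rho - expected) < 3 * se

    def test_mean_stays_at_mu(self):
        p = OUParams(theta=1.0, mu=3.0, beta_inv=1.0, x0=3.0)
        paths = simulate_ou(p, np.linspace(0, 10, 21), 2000, seed=3)
        assert np.abs(paths.mean(axis=0) - 3.0).max() < 3 * 1.0 / np.sqrt(2000)

    def test_deterministic_under_seed(self):
        p = OUParams(theta=1.0, mu=0.0, beta_inv=1.0, x0=0.0)
        t = np.linspace(0, 5, 6)
        assert np.array_equal(simulate_ou(p, t, 5, seed=4), simulate_ou(p, t, 5, seed=4))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_ou(OUParams(theta=-1.0, mu=0.0, beta_inv=1.0), [0, 1], 1)
        with pytest.raises(ValueError):
            simulate_ou(OUParams(theta=1.0, mu=0.0, beta_inv=1.0), [1, 0], 1)


class TestOuLoglik:
    def test_two_point_matches_hand_computed_density(self):
        theta, mu, beta_inv = 0.5, 2.0, 1.5
        p = OUParams(theta=theta, mu=mu, beta_inv=beta_inv)
        x0, x1, dt = 3.0, 2.5, 2.0
        m = mu + (x0 - mu) * np.exp(-theta * dt)
        v = (beta_inv / theta) * (1 - np.exp(-2 * theta * dt))
        expected = -0.5 * (np.log(2 * np.pi * v) + (x1 - m) ** 2 / v)
        assert ou_loglik(p, [0.0, dt], [x0, x1]) == pytest.approx(expected)

    def test_long_gap_transition_tends_to_stationary(self):
        p = OUParams(theta=1.0, mu=0.0, beta_inv=2.0)
        ll_gap = ou_loglik(p, [0.0, 1e4], [5.0, 0.7])
        sv = p.stationary_variance
        stat = -0.5 * (np.log(2 * np.pi * sv) + 0.7**2 / sv)
        assert ll_gap == pytest.approx(stat, abs=1e-8)

    def test_duplicate_times_rejected(self):
        p = OUParams(theta=1.0, mu=0.0, beta_inv=1.0)
        with pytest.raises(ValueError):
            ou_loglik(p, [0.0, 0.0, 1.0], [0.0, 0.1, 0.2])

    def test_true_params_beat_perturbed_on_long_path(self):
        p = OUParams(theta=0.5, mu=1.0, beta_inv=1.0, x0=1.0)
        t = np.linspace(0, 500, 1001)
        path = simulate_ou(p, t, 1, seed=5)[0]
        ll_true = ou_loglik(p, t, path)
        for bad in (
            OUParams(1.0, 1.0, 1.0),
            OUParams(0.5, 3.0, 1.0),
            OUParams(0.5, 1.0, 2.5),
        ):
            assert ll_true > ou_loglik(bad, t, path)


class TestFitOu:
    def test_parameter_recovery(self):
        truth = OUParams(theta=1.0, mu=5.0, beta_inv=1.0)
        rng = np.random.default_rng(6)
        times = np.linspace(0, 28, 15)
        rows = []
        for i in range(30):
            x0 = truth.mu + np.sqrt(truth.stationary_variance) * rng.standard_normal()
            p = OUParams(truth.theta, truth.mu, truth.beta_inv, x0=float(x0))
            rows += [
                (f"fast{i}", float(t), float(x), "fast")
                for t, x in zip(times, simulate_ou(p, times, 1, rng)[0])
            ]
        traj = TrajectorySet(
            pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"])
        )
        fit = fit_ou(traj)["fast"]
        assert fit.params.theta == pytest.approx(truth.theta, rel=0.25)
        assert fit.params.mu == pytest.approx(truth.mu, abs=0.3)
        assert fit.params.beta_inv == pytest.approx(truth.beta_inv, rel=0.25)

    def test_constant_trajectories_flagged_boundary(self):
        rows = []
        for i in range(3):
            for t in (0.0, 6.0, 12.0):
                rows.append((f"p{i}", t, 2.0, "slow"))
        traj = TrajectorySet(pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"]))
        with pytest.warns(UserWarning, match="constant"):
            fits = fit_ou(traj)
        assert fits["slow"].params.beta_inv == 0.0
        assert not fits["slow"].converged

    def test_too_few_patients_rejected(self):
        rows = [("p0", 0.0, 1.0, "fast"), ("p0", 6.0, 1.2, "fast")]
        traj = TrajectorySet(pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"]))
        with pytest.raises(ValueError):
            fit_ou(traj)


class TestBackcast:
    def test_bridge_endpoints_honored(self):
        p = OUParams(theta=0.3, mu=4.0, beta_inv=1.0)
        t, paths = backcast(p, x_at_zero=2.0, t_back_months=24, n_paths=50, seed=7)
        assert t[0] == pytest.approx(-24.0) and t[-1] == pytest.approx(0.0)
        assert np.allclose(paths[:, -1], 2.0)
        assert np.allclose(paths[:, 0], 0.0)

    def test_zero_noise_deterministic(self):
        p = OUParams(theta=0.3, mu=4.0, beta_inv=0.0)
        _, paths = backcast(p, x_at_zero=2.0, t_back_months=24, n_paths=5, seed=8)
        assert np.allclose(paths, paths[0][None, :])

    def test_interior_marginal_matches_analytic_bridge(self):
        """On a 3-point grid the bridge midpoint must follow the Gaussian
        conditional of the OU joint distribution given both endpoints."""
        theta, mu, beta_inv, b, T = 0.4, 1.0, 0.8, 2.0, 10.0
        p = OUParams(theta=theta, mu=mu, beta_inv=beta_inv)
        t, paths = backcast(p, x_at_zero=b, t_back_months=T, n_paths=4000, seed=9,
                            n_steps=2)
        mid = paths[:, 1]
        dt = T / 2
        c = np.exp(-theta * dt)
        v = (beta_inv / theta) * (1 - c**2)
        m1 = mu * (1 - c)  # from x0 = 0
        mean2 = mu + (m1 - mu) * c
        var2 = c**2 * v + v
        cov12 = v * c
        cond_mean = m1 + cov12 / var2 * (b - mean2)
        cond_var = v - cov12**2 / var2
        assert np.mean(mid) == pytest.approx(
            cond_mean, abs=3 * np.sqrt(cond_var / 4000)
        )
        assert np.var(mid, ddof=1) == pytest.approx(
            cond_var, abs=3 * cond_var * np.sqrt(2 / 3999)
        )

    def test_unconditioned_mode(self):
        p = OUParams(theta=0.3, mu=4.0, beta_inv=1.0)
        t, paths = backcast(p, x_at_zero=2.0, t_back_months=12, n_paths=20, seed=10,
                            bridge=False)
        assert paths.shape == (20, len(t))
        assert np.allclose(paths[:, 0], 0.0)
        assert not np.allclose(paths[:, -1], 2.0)  # endpoint free


class TestDownsample:
    def test_identity_on_full_grid(self):
        t = np.linspace(0, 10, 11)
        paths = simulate_ou(OUParams(1.0, 0.0, 1.0, 0.0), t, 4, seed=11)
        assert np.allclose(downsample_paths(paths, t, t), paths)

    def test_subset_selection(self):
        t = np.linspace(0, 10, 11)
        paths = simulate_ou(OUParams(1.0, 0.0, 1.0, 0.0), t, 4, seed=12)
        sub = downsample_paths(paths, t, [0.0, 5.0, 10.0])
        assert np.allclose(sub, paths[:, [0, 5, 10]])

    def test_outside_grid_rejected(self):
        t = np.linspace(0, 10, 11)
        paths = np.zeros((2, 11))
        with pytest.raises(ValueError):
            downsample_paths(paths, t, [12.0])


class TestVarianceBiomarker:
    def _two_group_traj(self, sd_fast, sd_slow, seed):
        rng = np.random.default_rng(seed)
        rows = []
        times = np.arange(0.0, 24.0, 6.0)
        for g, sd, n in (("fast", sd_fast, 6), ("slow", sd_slow, 5)):
            for i in range(n):
                states = np.cumsum(sd * rng.standard_normal(len(times)))
                rows += [(f"{g}{i}", float(t), float(x), g) for t, x in zip(times, states)]
        return TrajectorySet(pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"]))

    def test_noisier_group_detected(self):
        hits = 0
        for seed in range(20):
            traj = self._two_group_traj(3.0, 1.0, seed)
            hits += variance_biomarker(traj)["fast_slow_ratio"] > 1
        assert hits >= 19

    def test_symmetric_groups_ratio_near_one(self):
        ratios = [
            variance_biomarker(self._two_group_traj(1.0, 1.0, seed))["fast_slow_ratio"]
            for seed in range(30)
        ]
        assert 0.5 < np.median(ratios) < 2.0

    def test_single_visit_patient_excluded(self):
        rows = [("a", 0.0, 1.0, "fast"), ("a", 6.0, 2.0, "fast"), ("b", 0.0, 1.0, "fast"),
                ("c", 0.0, 0.0, "slow"), ("c", 6.0, 0.1, "slow")]
        traj = TrajectorySet(pd.DataFrame(rows, columns=["patient_id", "months", "state", "group"]))
        with pytest.warns(UserWarning, match="single visit"):
            out = variance_biomarker(traj)
        assert len(out["per_patient"]["fast"]) == 1


class TestPc1Trajectories:
    def test_sign_convention_and_grouping(self, small_cohort):
        _, matrix, metadata = small_cohort
        complete = impute_protein_means(matrix)
        traj = pc1_trajectories(complete, metadata)
        means = traj.data.groupby("group")["state"].mean()
        assert means["fast"] >= means["slow"]
        assert set(traj.data["patient_id"]) == set(metadata["patient_id"])

    def test_fast_paths_more_variable(self, small_cohort):
        _, matrix, metadata = small_cohort
        complete = impute_protein_means(matrix)
        traj = pc1_trajectories(complete, metadata)
        out = variance_biomarker(traj)
        assert out["fast_slow_ratio"] > 1.0

    def test_missing_values_rejected(self, small_cohort):
        _, matrix, metadata = small_cohort
        with pytest.raises(ValueError, match="impute"):
            pc1_trajectories(matrix, metadata)
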