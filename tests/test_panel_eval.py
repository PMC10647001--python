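import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from als_proteome_state.panel_eval import (
    bootstrap_auc_ci,
    evaluate_panel,
    exact_mann_whitney,
    fisher_exact_2x2,
    fit_logistic_panel,
    optimal_criterion,
    pca_project,
    roc_auc,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles


def fisher_oracle(table):
    """Enumerate all 2x2 tables with the observed margins; two-sided p is the
    total hypergeometric probability of tables no more likely than observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def mw_oracle(a, b):
    """Enumerate group assignments; U from pairwise comparisons (ties 1/2);
    two-sided p doubles the smaller tail."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(ga, gb):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=12),
        st.data(),
    )
    def test_negation_symmetry(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        s = np.array(scores)
        assert roc_auc(s, labels) + roc_auc(-s, labels) == pytest.approx(1.0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_discovery_sex_table(self):
        # 4M/2F fast vs 2M/3F slow
        assert fisher_exact_2x2([[4, 2], [2, 3]]) == pytest.approx(0.567100, abs=1e-6)

    def test_transposition_and_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t.T) == pytest.approx(p)
            assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])

    def test_against_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(0, 6, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_oracle(t), abs=1e-9)


class TestExactMannWhitney:
    def test_tied_pair(self):
        assert exact_mann_whitney([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_separated_triples(self):
        assert exact_mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_discovery_age_at_onset(self):
        slow = [43, 53, 31, 56, 34]
        fast = [56, 65, 54, 59, 52, 40]
        assert exact_mann_whitney(slow, fast) == pytest.approx(64 / 462)

    def test_single_value_per_group(self):
        assert exact_mann_whitney([1.0], [2.0]) == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 11 - na))
            a = rng.integers(0, 6, size=na).astype(float)  # integer data forces ties
            b = rng.integers(0, 6, size=nb).astype(float)
            assert exact_mann_whitney(a, b) == pytest.approx(mw_oracle(a, b), abs=1e-9)


class TestOptimalCriterion:
    def test_separated_scores(self):
        c, sens, spec = optimal_criterion([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < c <= 0.8

    def test_degenerate_scores(self):
        c, sens, spec = optimal_criterion([0.5] * 4, [0, 0, 1, 1])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_against_threshold_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.random(6)
            y = np.array([0, 0, 0, 1, 1, 1])
            c, sens, spec = optimal_criterion(s, y)
            best_j = max(
                (s[y == 1] >= t).mean() + (s[y == 0] < t).mean() - 1
                for t in np.concatenate([s, [s.max() + 1]])
            )
            assert sens + spec - 1 == pytest.approx(best_j)


class TestBootstrapCi:
    def test_separated_cohort_ci_is_one(self):
        y = np.array([0] * 20 + [1] * 20)
        s = y.astype(float)
        lo, hi = bootstrap_auc_ci(s, y, n_boot=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 10 + [1] * 10)
        s = rng.random(20)
        assert bootstrap_auc_ci(s, y, n_boot=200, seed=7) == bootstrap_auc_ci(
            s, y, n_boot=200, seed=7
        )

    def test_null_coverage(self):
        """95% interval should cover AUC=0.5 for label-independent scores in
        about 95% of replications (binomial slack at 100 reps)."""
        rng = np.random.default_rng(5)
        y = np.array([0] * 20 + [1] * 20)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            s = rng.random(40)
            lo, hi = bootstrap_auc_ci(s, y, n_boot=200, seed=rng)
            covered += lo <= 0.5 <= hi
        assert covered / n_rep >= 0.85

    def test_too_few_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_ci([1, 2], [0, 1], n_boot=10)


class TestLogisticPanel:
    def test_perfect_separation_flagged_auc_one(self):
        y = np.array([0] * 10 + [1] * 10)
        x = y.astype(float) + np.linspace(0, 0.1, 20)
        fit = fit_logistic_panel(x.reshape(-1, 1), y)
        assert fit.separated
        assert roc_auc(fit.scores, y) == pytest.approx(1.0)

    def test_null_marker_auc_near_half(self):
        """A label-independent marker scores at chance. The raw marker's AUC
        averages 0.5 exactly; in-sample fitted scores pick the marker's
        orientation, so their AUC sits at or slightly above 0.5."""
        rng = np.random.default_rng(6)
        y = np.array([0] * 50 + [1] * 50)
        raw_aucs, fit_aucs = [], []
        for _ in range(30):
            x = rng.standard_normal((100, 1))
            raw_aucs.append(roc_auc(x[:, 0], y))
            fit_aucs.append(roc_auc(fit_logistic_panel(x, y).scores, y))
        assert abs(np.mean(raw_aucs) - 0.5) < 0.05
        assert 0.5 <= np.mean(fit_aucs) < 0.62

    def test_affine_rescaling_leaves_auc_unchanged(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 15 + [1] * 15)
        x = rng.standard_normal((30, 1)) + y.reshape(-1, 1)
        a1 = roc_auc(fit_logistic_panel(x, y).scores, y)
        a2 = roc_auc(fit_logistic_panel(3.0 * x - 17.0, y).scores, y)
        assert a1 == pytest.approx(a2, abs=1e-6)

    def test_evaluate_panel_consistent(self):
        rng = np.random.default_rng(8)
        y = np.array([0] * 15 + [1] * 15)
        x = rng.standard_normal((30, 2)) + 1.5 * y.reshape(-1, 1)
        r = evaluate_panel(x, y, n_boot=200, seed=9)
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0 <= r.sensitivity <= 1 and 0 <= r.specificity <= 1


class TestPcaProject:
    def test_two_clusters_separate_on_pc1(self, tiny_matrix):
        values = tiny_matrix.values.copy()
        values[["s3", "s4", "s5"]] += 10.0
        scores, ratios = pca_project(
            tiny_matrix.with_values(values), n_components=2
        )
        left = scores.loc[["s0", "s1", "s2"], "PC1"].mean()
        right = scores.loc[["s3", "s4", "s5"], "PC1"].mean()
        assert abs(left - right) > 5.0
        assert ratios[0] > 0.8

    def test_protein_order_invariance(self, tiny_matrix):
        scores1, _ = pca_project(tiny_matrix, n_components=1)
        shuffled = tiny_matrix.with_values(tiny_matrix.values.iloc[::-1])
        scores2, _ = pca_project(shuffled, n_components=1)
        assert np.allclose(
            np.abs(scores1["PC1"].to_numpy()), np.abs(scores2["PC1"].to_numpy())
        )
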