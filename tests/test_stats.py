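"""Statistical layer: exact intervals, ROC/AUC, DeLong, routing, Fisher."""

import numpy as np
import pytest
from _oracles import mann_whitney_exact_p, pairwise_auc, rank_then_pearson
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from perfquant import (
    bonferroni_alpha,
    bootstrap_auc_ci,
    clopper_pearson,
    compare_groups,
    delong_test,
    fisher_exact_2xk,
    roc_curve,
    select_cutoffs,
    spearman_ci,
)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "successes,n,expected",
        [
            (16, 16, (0.794, 1.000)),
            (14, 14, (0.768, 1.000)),
            (12, 12, (0.735, 1.000)),
            (8, 8, (0.631, 1.000)),
            (10, 14, (0.419, 0.916)),
            (12, 16, (0.476, 0.927)),
            (10, 12, (0.516, 0.979)),
        ],
    )
    def test_exact_intervals_to_three_decimals(self, successes, n, expected):
        lo, hi = clopper_pearson(successes, n)
        assert round(lo, 3) == expected[0]
        assert round(hi, 3) == expected[1]

    def test_boundary_closed_forms(self):
        """At x = n the lower bound is (alpha/2)^(1/n) exactly; at x = 0
        the interval starts at 0 and ends at 1 - (alpha/2)^(1/n)."""
        for n in (5, 8, 12, 14, 16):
            lo, hi = clopper_pearson(n, n)
            assert lo == pytest.approx(0.025 ** (1 / n), abs=1e-10)
            assert hi == 1.0
            lo0, hi0 = clopper_pearson(0, n)
            assert lo0 == 0.0
            assert hi0 == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-10)

    def test_invalid_counts_rejected(self):
        for bad in [(5, 4), (-1, 4), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(*bad)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(1, 30))
    def test_interval_contains_point_estimate(self, x, n):
        if x > n:
            x = n
        lo, hi = clopper_pearson(x, n)
        assert 0.0 <= lo <= x / n <= hi <= 1.0


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_pairwise_oracle(self, seed):
        """Rank AUC with tie correction equals the mean over all
        case-control pairs of 1[case > control] + 0.5[tie]."""
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 20))
        scores = r.integers(0, 8, n).astype(float)  # integer scores force ties
        labels = np.zeros(n, dtype=bool)
        labels[r.choice(n, size=max(1, n // 3), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_negation_symmetry(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=20)
        labels = r.random(20) < 0.4
        labels[0], labels[1] = True, False
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_null_scores_give_half(self):
        r = np.random.default_rng(99)
        scores = r.normal(size=2000)
        labels = np.arange(2000) < 1000
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_cis_contain_auc(self):
        r = np.random.default_rng(3)
        roc = roc_curve(r.normal(size=30) + np.repeat([1.0, 0.0], 15), np.arange(30) < 15)
        for lo, hi in (roc.auc_ci_binomial, roc.auc_ci_delong):
            assert lo <= roc.auc <= hi


class TestBootstrap:
    def test_degenerate_perfect_separation(self):
        scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = [0, 0, 0, 1, 1, 1]
        assert bootstrap_auc_ci(scores, labels, n_boot=200, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self):
        r = np.random.default_rng(4)
        scores = r.normal(size=30) + np.repeat([1.0, 0.0], 15)
        labels = np.arange(30) < 15
        a = bootstrap_auc_ci(scores, labels, n_boot=300, seed=7)
        b = bootstrap_auc_ci(scores, labels, n_boot=300, seed=7)
        assert a == b

    def test_monte_carlo_stability(self):
        r = np.random.default_rng(5)
        scores = r.normal(size=30) + np.repeat([1.2, 0.0], 15)
        labels = np.arange(30) < 15
        a = bootstrap_auc_ci(scores, labels, n_boot=1000, seed=1)
        b = bootstrap_auc_ci(scores, labels, n_boot=2000, seed=2)
        assert a[0] == pytest.approx(b[0], abs=0.02)
        assert a[1] == pytest.approx(b[1], abs=0.02)


class TestDelong:
    def test_self_comparison(self):
        r = np.random.default_rng(6)
        scores = r.normal(size=30) + np.repeat([0.8, 0.0], 15)
        labels = np.arange(30) < 15
        auc_a, auc_b, z, p = delong_test(scores, scores, labels)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_aucs_match_roc_curve(self):
        r = np.random.default_rng(7)
        labels = np.arange(30) < 16
        s_a = r.normal(size=30) + labels
        s_b = r.normal(size=30) + 0.5 * labels
        auc_a, auc_b, _, _ = delong_test(s_a, s_b, labels)
        assert auc_a == pytest.approx(roc_curve(s_a, labels).auc)
        assert auc_b == pytest.approx(roc_curve(s_b, labels).auc)

    def test_agrees_with_paired_bootstrap(self):
        """DeLong p agrees in direction and within 0.05 with a 10,000-rep
        stratified paired-bootstrap test of the AUC difference."""
        r = np.random.default_rng(8)
        n1, n0 = 16, 14
        labels = np.arange(n1 + n0) < n1
        base = r.normal(size=n1 + n0) + 1.1 * labels
        s_a = base + 0.4 * r.normal(size=n1 + n0)
        s_b = base + 1.1 * r.normal(size=n1 + n0)
        _, _, _, p = delong_test(s_a, s_b, labels)

        def auc(s, lab):
            return pairwise_auc_fast(s, lab)

        def pairwise_auc_fast(s, lab):
            ranks = sps.rankdata(s)
            m = lab.sum()
            return (ranks[lab].sum() - m * (m + 1) / 2) / (m * (lab.size - m))

        rb = np.random.default_rng(9)
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        diffs = np.empty(10_000)
        for b in range(10_000):
            idx = np.concatenate(
                [pos_idx[rb.integers(0, n1, n1)], neg_idx[rb.integers(0, n0, n0)]]
            )
            lab = labels[idx]
            diffs[b] = auc(s_a[idx], lab) - auc(s_b[idx], lab)
        obs = roc_curve(s_a, labels).auc - roc_curve(s_b, labels).auc
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert np.sign(obs) == np.sign(np.median(diffs)) or obs == 0
        assert p == pytest.approx(min(p_boot, 1.0), abs=0.05)

    def test_zero_variance_with_unequal_aucs_raises(self):
        # perfectly separated vs perfectly anti-separated: all placement
        # values are constant, so the difference has zero variance
        labels = np.array([1, 1, 0, 0], dtype=bool)
        with pytest.raises(ValueError):
            delong_test([10, 11, 1, 2], [1, 2, 10, 11], labels)


class TestSelectCutoffs:
    @pytest.fixture()
    def clinical_like(self):
        """Score layout reproducing the published confusion matrices:
        12 clearly positive cases, 4 overlapping cases, 4 high controls."""
        controls = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 16, 17, 18], dtype=float)
        cases = np.array([11, 12, 13, 14] + list(range(30, 42)), dtype=float)
        scores = np.concatenate([cases, controls])
        labels = np.concatenate([np.ones(16, bool), np.zeros(14, bool)])
        return scores, labels

    def test_youden_matrix(self, clinical_like):
        roc = roc_curve(*clinical_like)
        youden, _ = select_cutoffs(roc)
        assert (youden.tp, youden.fn, youden.fp, youden.tn) == (12, 4, 0, 14)
        assert youden.sensitivity == 0.75
        assert youden.specificity == 1.0
        assert round(youden.sens_ci[0], 3) == 0.476
        assert round(youden.sens_ci[1], 3) == 0.927
        assert round(youden.spec_ci[0], 3) == 0.768
        assert youden.spec_ci[1] == 1.0

    def test_screening_matrix(self, clinical_like):
        roc = roc_curve(*clinical_like)
        _, screening = select_cutoffs(roc)
        assert (screening.tp, screening.fn, screening.fp, screening.tn) == (16, 0, 4, 10)
        assert screening.sensitivity == 1.0
        assert screening.specificity == pytest.approx(10 / 14)
        assert round(screening.sens_ci[0], 3) == 0.794
        assert round(screening.spec_ci[0], 3) == 0.419
        assert round(screening.spec_ci[1], 3) == 0.916

    def test_screening_is_largest_full_sensitivity_cutoff(self, clinical_like):
        scores, labels = clinical_like
        roc = roc_curve(scores, labels)
        _, screening = select_cutoffs(roc)
        assert screening.cutoff_value == pytest.approx(10.5)  # midpoint of 10 and 11

    def test_perfect_classifier(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        youden, screening = select_cutoffs(roc)
        assert youden.sensitivity == 1.0 and youden.specificity == 1.0
        assert screening.sensitivity == 1.0


class TestSpearman:
    def test_monotone_gives_one(self):
        x = np.arange(10.0)
        r_s, lo, hi, p = spearman_ci(x, x**3 + 2)
        assert r_s == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=16)
        y = rng.normal(size=16) + 0.7 * x
        r1 = spearman_ci(x, y)[0]
        r2 = spearman_ci(x, -y)[0]
        assert r1 == pytest.approx(-r2)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_rank_then_pearson(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 10, 16).astype(float)  # ties exercised
        y = r.integers(0, 10, 16).astype(float)
        r_s = spearman_ci(x, y)[0]
        assert r_s == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_fisher_z_interval_formula(self, rng):
        x = rng.normal(size=16)
        y = 0.6 * x + rng.normal(size=16)
        r_s, lo, hi, _ = spearman_ci(x, y)
        z = np.arctanh(r_s)
        half = sps.norm.ppf(0.975) / np.sqrt(16 - 3)
        assert lo == pytest.approx(np.tanh(z - half))
        assert hi == pytest.approx(np.tanh(z + half))
        lo_f, hi_f = spearman_ci(x, y, fieller=True)[1:3]
        assert lo_f < lo and hi_f > hi  # Fieller inflation widens the CI

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestBonferroni:
    def test_values(self):
        assert bonferroni_alpha(0.05, 9) == pytest.approx(0.05 / 9)
        assert f"{bonferroni_alpha(0.05, 9):.4f}" == "0.0056"
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.10, 4) == 0.025
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCompareGroups:
    def test_normal_data_routes_to_t_test(self):
        r = np.random.default_rng(20)
        vals = np.concatenate([r.normal(0, 1, 20), r.normal(1, 1, 20)])
        labels = np.repeat(["a", "b"], 20)
        res = compare_groups(vals, labels)
        assert res.test_name == "t_test"
        assert "mean" in res.group_summaries["a"]
        assert all(p >= 0.05 for p in res.normality_p.values())

    def test_skewed_data_routes_to_mann_whitney(self):
        r = np.random.default_rng(21)
        vals = np.concatenate([r.exponential(1, 20) ** 2, r.exponential(2, 20) ** 2])
        labels = np.repeat(["a", "b"], 20)
        res = compare_groups(vals, labels)
        assert res.test_name == "mann_whitney"
        assert "median" in res.group_summaries["a"]

    def test_symmetric_case_p_is_one(self):
        # U equals its null mean, so the exact two-sided p is 1
        res = compare_groups(
            [1.0, 4.0, 7.0, 2.0, 3.0, 5.0, 6.0], ["a", "a", "a", "b", "b", "b", "b"]
        )
        if res.test_name == "mann_whitney":
            assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [30, 31])
    def test_exact_p_matches_enumeration(self, seed):
        """Small-sample Mann-Whitney p equals full permutation enumeration."""
        r = np.random.default_rng(seed)
        a = r.permutation(100)[:5].astype(float)
        b = r.permutation(100)[50:55].astype(float) + 0.5
        vals = np.concatenate([a**3, b**3])  # skewed to force MW routing
        labels = np.repeat(["x", "y"], 5)
        res = compare_groups(vals, labels)
        if res.test_name == "mann_whitney":
            assert res.p_value == pytest.approx(
                mann_whitney_exact_p(vals[:5], vals[5:]), abs=1e-9
            )

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0] * 8, ["a"] * 4 + ["b"] * 4)


class TestFisherExact:
    def test_published_sex_table(self):
        assert round(fisher_exact_2xk([[6, 10], [5, 9]]), 2) == 1.0

    @pytest.mark.parametrize(
        "table",
        [
            [[6, 10], [5, 9]],
            [[1, 9], [8, 2]],
            [[12, 4], [0, 14]],
            [[3, 3], [3, 3]],
        ],
    )
    def test_2x2_matches_scipy(self, table):
        assert fisher_exact_2xk(table) == pytest.approx(
            sps.fisher_exact(table).pvalue, abs=1e-10
        )

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1, 4], [2, 5, 1]], 0.1452991),
            ([[1, 9, 3], [11, 2, 4]], 0.001110481),
        ],
    )
    def test_2x3_freeman_halton_reference(self, table, expected):
        """2 x k enumeration matches an independent Freeman-Halton
        implementation (reference values frozen from R's fisher.test)."""
        assert fisher_exact_2xk(table) == pytest.approx(expected, abs=1e-6)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk([[1, 2, 3]])
        with pytest.raises(ValueError):
            fisher_exact_2xk([[0, 0], [0, 0]])
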