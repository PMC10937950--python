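"""Evaluation statistics: accuracy CI, ROC/AUC, Mann-Whitney, KM, Cox."""

import itertools

import numpy as np
import pandas as pd
import pytest

from evglyco.evaluate import (accuracy_ci, cox_ph, km_logrank, mann_whitney_u,
                              roc_auc)


class TestAccuracyCI:
    def test_all_correct_n20_exact_lower_bound(self):
        acc, (lo, hi) = accuracy_ci(np.diag([8, 7, 5]))
        assert acc == 1.0
        assert hi == 1.0
        # exact binomial: lower bound = alpha^(1/n) = 0.025^(1/20)
        assert lo == pytest.approx(0.025 ** (1 / 20), rel=1e-9)

    def test_diagonal_matrix_is_perfect(self):
        acc, _ = accuracy_ci(np.diag([3, 3, 3, 3]))
        assert acc == 1.0

    def test_uniform_random_predictions_near_one_over_k(self):
        rng = np.random.default_rng(0)
        k = 3
        truth = rng.integers(0, k, 3000)
        pred = rng.integers(0, k, 3000)
        cm = np.zeros((k, k))
        for t, p in zip(truth, pred):
            cm[t, p] += 1
        acc, _ = accuracy_ci(cm)
        assert abs(acc - 1 / k) < 0.03

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy_ci(np.zeros((2, 2)))


class TestROC:
    def test_perfect_separation(self):
        auc, (lo, hi) = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0 and hi == 1.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(500):
            scores = rng.standard_normal(60)
            labels = np.zeros(60, dtype=int)
            labels[rng.choice(60, 30, replace=False)] = 1
            aucs.append(roc_auc(scores, labels)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        assert roc_auc(-scores, labels)[0] == pytest.approx(
            1 - roc_auc(scores, labels)[0], abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(50)
        labels = (scores + rng.standard_normal(50) > 0).astype(int)
        a1 = roc_auc(scores, labels)[0]
        a2 = roc_auc(np.exp(2.0 * scores) + 5, labels)[0]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.standard_normal(80)
        labels = (rng.random(80) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels)[0] == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestMannWhitney:
    def test_identical_samples_give_half_u(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        u, _ = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2

    def test_fully_separated_samples(self):
        u_low, _ = mann_whitney_u([1, 2, 3], [10, 11, 12])
        u_high, _ = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u_low == 0.0 and u_high == 9.0

    def test_exact_p_matches_enumeration_n5(self):
        """Brute-force oracle: full permutation distribution of U for
        n1 = n2 = 5 without ties."""
        x = np.array([1.2, 3.4, 0.5, 7.1, 2.2])
        y = np.array([4.4, 6.0, 0.9, 5.5, 8.8])
        u_obs, p_obs = mann_whitney_u(x, y)

        combined = np.concatenate([x, y])
        n1 = len(x)
        us = []
        for idx in itertools.combinations(range(len(combined)), n1):
            gx = combined[list(idx)]
            gy = np.delete(combined, list(idx))
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in gx for yj in gy)
            us.append(u)
        us = np.array(us)
        p_lo = (us <= u_obs).mean()
        p_hi = (us >= u_obs).mean()
        p_exact = min(1.0, 2 * min(p_lo, p_hi))
        assert p_obs == pytest.approx(p_exact, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKaplanMeier:
    def test_exponential_median_recovered(self):
        rng = np.random.default_rng(0)
        lam = 1 / 100.0
        n = 4000
        df = pd.DataFrame({
            "time": rng.exponential(1 / lam, n),
            "event": np.ones(n, dtype=int),
            "signature_group": ["all"] * n,
        })
        res = km_logrank(df)
        assert res.medians["all"] == pytest.approx(np.log(2) / lam, rel=0.05)

    def test_all_censored_has_undefined_median(self):
        df = pd.DataFrame({
            "time": [10.0, 20.0, 30.0, 5.0],
            "event": [0, 0, 0, 1],
            "signature_group": ["g", "g", "g", "h"],
        })
        res = km_logrank(df)
        assert np.isinf(res.medians["g"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                           "signature_group": ["a", "b"]})
        with pytest.raises(ValueError):
            km_logrank(df)

    def test_null_logrank_type_one_error(self):
        """Identical exponential groups: ~5% of 1000 null replicates reject
        at alpha = 0.05 (binomial 3-sigma band)."""
        rng = np.random.default_rng(1)
        rejections = 0
        n = 30
        for _ in range(1000):
            df = pd.DataFrame({
                "time": rng.exponential(100.0, 2 * n),
                "event": np.ones(2 * n, dtype=int),
                "signature_group": ["a"] * n + ["b"] * n,
            })
            rejections += km_logrank(df).logrank_p < 0.05
        assert 29 <= rejections <= 71


class TestCox:
    def test_null_covariate_hazard_ratio_near_one(self):
        rng = np.random.default_rng(2)
        n = 400
        df = pd.DataFrame({
            "time": rng.exponential(100.0, n),
            "event": np.ones(n, dtype=int),
            "x": rng.standard_normal(n),
        })
        fit = cox_ph(df, ["x"])
        assert fit.loc["x", "HR"] == pytest.approx(1.0, abs=0.15)
        assert fit.loc["x", "ci_low"] < 1.0 < fit.loc["x", "ci_high"]

    def test_multivariate_adjustment_runs(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        lam = 0.01 * np.exp(0.8 * x)
        df = pd.DataFrame({"time": rng.exponential(1 / lam), "event": 1,
                           "x": x, "z": z})
        fit = cox_ph(df, ["x", "z"], mode="multi")
        assert fit.loc["x", "HR"] == pytest.approx(np.exp(0.8), rel=0.15)
        assert fit.loc["z", "p"] > 0.01

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
                           "x": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            cox_ph(df, ["x"])

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_ph(df, ["x", "x"], mode="multi")
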