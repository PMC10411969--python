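"""Rank statistics, BH correction and diagonal LDA against independent oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from mirrorcode.stats import (
    bh_reject,
    diag_lda_fit,
    diag_lda_predict,
    friedman,
    kruskal_wallis,
    rank_sum,
    rank_sum_matrix,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent code paths: naive loops, no shared helpers)
# ---------------------------------------------------------------------------

def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def kw_oracle(groups):
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t**3 - t
    denom = 1.0 - ties / (n**3 - n)
    return 0.0 if denom <= 0 else h / denom


def friedman_oracle(mat):
    n, k = len(mat), len(mat[0])
    colsums = [0.0] * k
    ties = 0.0
    for row in mat:
        r = midranks(list(row))
        for j in range(k):
            colsums[j] += r[j]
        for v in set(row):
            t = list(row).count(v)
            ties += t**3 - t
    stat = 12.0 / (n * k * (k + 1)) * sum(s**2 for s in colsums) - 3.0 * n * (k + 1)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    return 0.0 if denom <= 0 else stat / denom


def ranksum_exact_p(a, b):
    """Exact two-sided p by enumerating all label assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = midranks(pooled)
    w_obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in comb)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def lda_oracle_predict(xtr, ytr, xte):
    """Naive pooled-diagonal Gaussian classifier with full log densities."""
    classes = sorted(set(ytr))
    d = xtr.shape[1]
    means = {c: xtr[ytr == c].mean(axis=0) for c in classes}
    sse = np.zeros(d)
    for c in classes:
        sse += ((xtr[ytr == c] - means[c]) ** 2).sum(axis=0)
    var = np.maximum(sse / (len(ytr) - len(classes)), 1e-9)
    priors = {c: np.mean(ytr == c) for c in classes}
    preds = []
    for x in xte:
        best, best_ll = None, -np.inf
        for c in classes:
            ll = float(
                -0.5 * np.sum((x - means[c]) ** 2 / var + np.log(2 * np.pi * var))
                + np.log(priors[c])
            )
            if ll > best_ll:  # strict: ties keep the lowest class
                best, best_ll = c, ll
        preds.append(best)
    return np.array(preds)


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_statistic(self):
        h, _ = kruskal_wallis([np.array([1, 2]), np.array([3, 4])])
        assert np.isclose(h, 2.4)

    def test_identical_groups(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(4), np.ones(6)])
        assert h == 0.0 and p == 1.0

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = rng.integers(2, 5)
            groups = [
                np.round(rng.normal(size=rng.integers(3, 8)), 1) for _ in range(k)
            ]
            h, p = kruskal_wallis(groups)
            assert np.isclose(h, kw_oracle([g.tolist() for g in groups]), atol=1e-10)
            if np.ptp(np.concatenate(groups)) > 0:
                h_sp, p_sp = sps.kruskal(*groups)
                assert np.isclose(h, h_sp, atol=1e-10)
                assert np.isclose(p, p_sp, atol=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=6) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g * 2) for g in groups])
        assert np.isclose(h1, h2)


class TestFriedman:
    def test_consistent_ordering(self):
        chi2, _ = friedman(np.array([[1, 2, 3], [4, 5, 6], [1, 3, 9]]))
        assert np.isclose(chi2, 6.0)

    def test_all_equal(self):
        chi2, p = friedman(np.full((4, 3), 7.0))
        assert chi2 == 0.0 and p == 1.0

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            mat = np.round(rng.normal(size=(5, 4)), 1)
            chi2, p = friedman(mat)
            assert np.isclose(chi2, friedman_oracle(mat.tolist()), atol=1e-10)
            if not np.isclose(chi2, 0.0):
                chi2_sp, p_sp = sps.friedmanchisquare(*mat.T)
                assert np.isclose(chi2, chi2_sp, atol=1e-8)
                assert np.isclose(p, p_sp, atol=1e-8)


class TestRankSum:
    def test_identical_samples(self):
        assert rank_sum(np.arange(5), np.arange(5)) > 0.9

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(size=9)
        assert np.isclose(rank_sum(a, b), rank_sum(b, a))

    def test_extreme_separation_near_exact(self):
        a, b = np.array([1, 2, 3, 4]), np.array([10, 11, 12, 13])
        p = rank_sum(a, b)
        exact = ranksum_exact_p(a.tolist(), b.tolist())  # 2/70
        assert np.isclose(exact, 2 / 70)
        assert abs(p - exact) < 0.01  # normal approximation vs enumeration

    def test_close_to_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = np.round(rng.normal(size=5), 1)
            b = np.round(rng.normal(size=5), 1)
            p = rank_sum(a, b)
            exact = ranksum_exact_p(a.tolist(), b.tolist())
            # the normal approximation is loosest deep in the null (p near 1)
            tol = 0.04 if exact <= 0.5 else 0.10
            assert abs(p - exact) < tol

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            a = np.round(rng.normal(size=rng.integers(4, 12)), 1)
            b = np.round(rng.normal(size=rng.integers(4, 12)), 1)
            p = rank_sum(a, b)
            p_sp = sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert np.isclose(p, p_sp, atol=1e-9)

    def test_matrix_variant_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 12))
        pm = rank_sum_matrix(x, 5)
        for i in range(20):
            assert np.isclose(pm[i], rank_sum(x[i, :5], x[i, 5:]))


class TestBH:
    def test_all_below_stepup_thresholds(self):
        rej = bh_reject(np.array([0.001, 0.02, 0.04]), alpha=0.05, m=3)
        assert rej.all()

    def test_all_ones(self):
        assert not bh_reject(np.ones(10)).any()

    def test_single_test(self):
        assert bh_reject(np.array([0.049]), alpha=0.05, m=1)[0]

    def test_alpha_zero_rejects_nothing(self):
        rng = np.random.default_rng(8)
        assert not bh_reject(rng.uniform(size=50), alpha=0.0).any()

    def test_rejections_are_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        rej = bh_reject(p, alpha=0.2)
        if rej.any():
            assert p[rej].max() <= p[~rej].min() or not (~rej).any()

    def test_padding_family_never_unrejects(self):
        """With the family size held fixed, appending p=1 tests cannot turn a
        rejection into an acceptance."""
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 0.2, size=30)
        m = 60
        base = bh_reject(p, alpha=0.05, m=m)
        padded = bh_reject(np.concatenate([p, np.ones(20)]), alpha=0.05, m=m)[:30]
        assert not (base & ~padded).any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_reject(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_reject(np.array([0.5]), m=0)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(2, 40))
            mine = bh_reject(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mine, ref)


class TestDiagLDA:
    def test_fit_means_and_pooled_variance(self):
        model = diag_lda_fit(np.array([[0.0], [2.0], [8.0], [10.0]]),
                             np.array([0, 0, 1, 1]))
        assert np.allclose(model.class_means.ravel(), [1.0, 9.0])
        assert np.isclose(model.pooled_var[0], 2.0)  # (2+2)/(4-2)

    def test_zero_variance_floored(self):
        model = diag_lda_fit(np.array([[0.0], [0.0], [10.0], [10.0]]),
                             np.array([0, 0, 1, 1]))
        assert model.pooled_var[0] == pytest.approx(1e-9)

    def test_balanced_priors(self):
        x = np.arange(24, dtype=float).reshape(24, 1)
        y = np.repeat([0, 1, 2], 8)
        model = diag_lda_fit(x, y)
        assert np.allclose(model.priors, 1 / 3)

    def test_predict_nearer_mean_and_tie_rule(self):
        model = diag_lda_fit(np.array([[0.0], [2.0], [8.0], [10.0]]),
                             np.array([0, 0, 1, 1]))
        assert diag_lda_predict(model, [[2.0]])[0] == 0
        assert diag_lda_predict(model, [[5.0]])[0] == 0  # equidistant -> lowest

    def test_scale_consistency(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, size=30)
        y[:6] = [0, 0, 1, 1, 2, 2]
        xt = rng.normal(size=(10, 4))
        m1 = diag_lda_fit(x, y)
        m2 = diag_lda_fit(x * 7.5, y)
        assert np.array_equal(diag_lda_predict(m1, xt), diag_lda_predict(m2, xt * 7.5))

    def test_matches_log_likelihood_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            xtr = rng.normal(size=(18, 5)) + rng.normal(size=(1, 5))
            ytr = np.repeat([0, 1, 2], 6)
            xte = rng.normal(size=(8, 5))
            model = diag_lda_fit(xtr, ytr)
            assert np.array_equal(
                diag_lda_predict(model, xte), lda_oracle_predict(xtr, ytr, xte)
            )
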