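"""stats primitives against independent from-definition oracles."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from immunopanel.stats import (auc, auc_batch, delong_compare, fit_logistic,
                               fit_logistic_batch, km_estimate, logrank_test,
                               wilcoxon_de_test)

# ---------------------------------------------------------------------------
# independent oracles, coded from the definitions
# ---------------------------------------------------------------------------


def auc_pair_counting(scores, labels):
    """O(n^2) Mann-Whitney AUC with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def km_product_limit(times, events):
    """Product-limit estimator straight from the definition."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    surv = {}
    s = 1.0
    for ut in np.unique(t):
        at_risk = np.sum(t >= ut)
        deaths = np.sum((t == ut) & (e == 1))
        s *= 1.0 - deaths / at_risk
        surv[ut] = s
    return surv


def logrank_by_hand(times, events, group):
    """Two-group log-rank statistic by 2x2 hypergeometric accumulation."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    o_minus_e, var = 0.0, 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n_tot = at_risk.sum()
        n1 = (at_risk & (g == g[0])).sum()
        d_tot = ((t == ut) & (e == 1)).sum()
        d1 = ((t == ut) & (e == 1) & (g == g[0])).sum()
        o_minus_e += d1 - d_tot * n1 / n_tot
        if n_tot > 1:
            var += (d_tot * (n1 / n_tot) * (1 - n1 / n_tot)
                    * (n_tot - d_tot) / (n_tot - 1))
    return o_minus_e ** 2 / var


def wilcoxon_exact_enumeration(x, y):
    """Exact signed-rank two-sided p over all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    m = n * (n + 1) / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = ranks[np.array(signs, dtype=bool)].sum()
        if abs(t - m / 2.0) >= abs(t_obs - m / 2.0) - 1e-12:
            count += 1
    return count / 2.0 ** n


def _random_survival(rng, n):
    times = rng.integers(1, 15, size=n).astype(float)
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return times, events


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 61))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = auc(scores, labels).auc
        assert got == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)


def test_auc_trivial_cases():
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
    assert auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5
    with pytest.raises(ValueError):
        auc([1, 2, 3], [1, 1, 1])


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    a = auc(scores, labels).auc
    b = auc(np.exp(3 * scores) + 7, labels).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = np.round(rng.normal(size=80), 1)
    labels = (rng.random(80) < 0.5).astype(int)
    assert auc(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


def test_delong_identity_and_monotone():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=60)
    labels = (rng.random(60) < 0.5).astype(int)
    assert delong_compare(scores, scores, labels) == 1.0
    assert delong_compare(scores, np.tanh(scores) * 5 + 1, labels) == 1.0


def test_delong_type_one_error_calibration():
    """Under H0 (equal-AUC correlated scores) rejections at 0.05 stay nominal."""
    rng = np.random.default_rng(7)
    n, n_sim = 200, 500
    rejections = 0
    for _ in range(n_sim):
        latent = rng.normal(size=n)
        labels = (rng.random(n) < sps.norm.cdf(latent)).astype(int)
        if labels.min() == labels.max():
            continue
        a = latent + rng.normal(scale=1.0, size=n)
        b = latent + rng.normal(scale=1.0, size=n)
        if delong_compare(a, b, labels) < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07


def test_delong_degenerate_variance_raises():
    labels = np.array([0, 0, 1, 1])
    with pytest.raises(ValueError, match="degenerate"):
        delong_compare([0, 0, 1, 1], [0, 0, 0, 0], labels)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def test_km_trivial_cases():
    flat = km_estimate([5, 8], [0, 0])
    assert np.all(flat.survival_prob == 1.0)
    curve = km_estimate([1, 2], [1, 1])
    assert curve.survival_at(1.5) == pytest.approx(0.5)
    assert curve.survival_at(2.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_km_matches_product_limit_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(5, 31))
        times, events = _random_survival(rng, n)
        curve = km_estimate(times, events)
        for ut, s in km_product_limit(times, events).items():
            assert curve.survival_at(ut) == pytest.approx(s, abs=1e-10)


def test_km_curve_monotone_from_one(rng):
    times, events = _random_survival(rng, 40)
    curve = km_estimate(times, events)
    assert curve.survival_prob[0] == 1.0
    assert np.all(np.diff(curve.survival_prob) <= 1e-12)


def test_logrank_identical_groups_is_null():
    times = [1, 2, 3, 4, 1, 2, 3, 4]
    events = [1, 0, 1, 1, 1, 0, 1, 1]
    group = [0, 0, 0, 0, 1, 1, 1, 1]
    res = logrank_test(times, events, group)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == pytest.approx(1.0, abs=1e-10)


def test_logrank_matches_hand_accumulation(rng):
    for _ in range(100):
        n = int(rng.integers(8, 25))
        times, events = _random_survival(rng, n)
        group = rng.integers(0, 2, size=n)
        if group.min() == group.max():
            group[0] = 1 - group[0]
        got = logrank_test(times, events, group)
        want = logrank_by_hand(times, events, group)
        assert got.statistic == pytest.approx(want, abs=1e-8)
        assert got.p_value == pytest.approx(sps.chi2.sf(want, 1), abs=1e-8)


def test_logrank_label_swap_invariance(rng):
    times, events = _random_survival(rng, 20)
    group = rng.integers(0, 2, size=20)
    group[0] = 1 - group[0]
    a = logrank_test(times, events, group)
    b = logrank_test(times, events, 1 - group)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


def test_logrank_agrees_with_permutation_null():
    rng = np.random.default_rng(3)
    times = np.array([2, 5, 3, 8, 1, 9, 4, 7, 6, 10, 11, 12], dtype=float)
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
    group = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
    obs = logrank_by_hand(times, events, group)
    perm = np.empty(10_000)
    for i in range(perm.size):
        perm[i] = logrank_by_hand(times, events, rng.permutation(group))
    p_perm = float(np.mean(perm >= obs - 1e-12))
    p_chi2 = logrank_test(times, events, group).p_value
    mc_se = np.sqrt(p_perm * (1 - p_perm) / perm.size)
    # chi-square approximation at n=12 plus Monte-Carlo error
    assert abs(p_chi2 - p_perm) < 0.03 + 4 * mc_se


def test_logrank_errors():
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])  # one group
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])  # no events


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------


def test_wilcoxon_paired_identical_raises():
    x = np.arange(8.0)
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_de_test(x, x, paired=True)


def test_wilcoxon_small_n_matches_exact_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(6, 11))
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.8, size=n) + 0.3
        got = wilcoxon_de_test(x, y, paired=True)
        want = wilcoxon_exact_enumeration(x, y)
        assert got == pytest.approx(want, abs=1e-10)


def test_wilcoxon_detects_large_shift():
    """A two-pooled-SD shift at n=50 is essentially always significant."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = rng.normal(loc=2.0, size=50)
        if wilcoxon_de_test(x, y, paired=False) < 0.05:
            hits += 1
    assert hits >= 9


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def test_logistic_2x2_closed_form(rng):
    """On a binary predictor the MLE slope is the log odds ratio."""
    for _ in range(25):
        a, b, c, d = rng.integers(3, 30, size=4)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        model = fit_logistic(x[:, None], y)
        assert model.converged and not model.penalized
        assert model.coefficients[0] == pytest.approx(
            np.log(a * d / (b * c)), abs=1e-6)
        assert model.intercept == pytest.approx(np.log(c / d), abs=1e-6)


def test_logistic_matches_statsmodels(rng):
    X = rng.standard_normal((120, 4))
    y = (rng.random(120) < sps.norm.cdf(X[:, 0])).astype(float)
    model = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.allclose(np.r_[model.intercept, model.coefficients],
                       ref.params, atol=1e-7)
    assert model.aic == pytest.approx(ref.aic, abs=1e-6)


def test_logistic_null_data_small_coefficients(rng):
    X = rng.standard_normal((500, 3))
    y = (rng.random(500) < 0.5).astype(float)
    model = fit_logistic(X, y)
    assert np.all(np.abs(model.coefficients) < 0.3)
    assert auc(model.predicted_prob, y).auc < 0.6


def test_logistic_separation_falls_back_to_ridge():
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    model = fit_logistic(x[:, None], y)
    assert model.penalized
    assert np.isfinite(model.coefficients).all()
    assert model.predicted_prob.min() > 0 and model.predicted_prob.max() < 1


def test_logistic_single_class_raises():
    with pytest.raises(ValueError):
        fit_logistic(np.ones((5, 1)), np.ones(5))


def test_logistic_aic_drops_with_planted_predictor():
    """Adding a truly predictive gene lowers AIC relative to the null model."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        y = (rng.random(200) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
        if y.min() == y.max():
            continue
        p1 = y.mean()
        aic_null = 2.0 - 2.0 * (y.sum() * np.log(p1)
                                + (y.size - y.sum()) * np.log(1 - p1))
        if fit_logistic(x[:, None], y).aic < aic_null:
            wins += 1
    assert wins >= 15


def test_batch_fit_agrees_with_single_fits(rng):
    X = rng.standard_normal((150, 6))
    y = (rng.random(150) < sps.norm.cdf(X[:, 1] - X[:, 4])).astype(float)
    subsets = np.array([[0, 1], [2, 3], [1, 4], [0, 5]])
    res = fit_logistic_batch(X, y, subsets, tol=1e-10)
    for i, sub in enumerate(subsets):
        single = fit_logistic(X[:, sub], y)
        assert np.allclose(res["beta"][i],
                           np.r_[single.intercept, single.coefficients],
                           atol=1e-7)
        assert res["auc"][i] == pytest.approx(
            auc(single.predicted_prob, y).auc, abs=1e-9)


def test_auc_batch_matches_scalar(rng):
    scores = np.round(rng.normal(size=(5, 40)), 1)
    labels = (rng.random(40) < 0.5).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    batch = auc_batch(scores, labels)
    for i in range(5):
        assert batch[i] == pytest.approx(auc(scores[i], labels).auc, abs=1e-12)
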