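"""Statistical primitives shared by every stage of the pipeline.

Survival estimation and the log-rank test are delegated to lifelines; the
Wilcoxon tests to scipy. Logistic regression is a small batched Newton
(IRLS) solver written here because the combination-benchmarking and
exhaustive-search stages fit on the order of a million small logistic
models and need fits that are vectorized across models sharing one
response vector. The DeLong AUC variance and the paired DeLong comparison
are implemented from the structural-component decomposition.

Conventions:

* The binary response throughout is vital status (1 = dead, 0 = alive);
  follow-up time is ignored once a patient is dichotomized. Time-aware
  models (Cox, time-dependent ROC) are deliberately out of scope.
* Tied scores receive 0.5 credit in the AUC (Mann-Whitney convention).
* Perfectly separable logistic problems fall back to a small fixed ridge
  penalty and are flagged via ``LogisticModel.penalized``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "LogisticModel",
    "RocResult",
    "km_estimate",
    "logrank_test",
    "wilcoxon_de_test",
    "fit_logistic",
    "fit_logistic_batch",
    "auc",
    "delong_compare",
]

#: ridge penalty used when an unpenalized fit separates; kept fixed and small
FALLBACK_RIDGE = 0.1

#: coefficient magnitude beyond which an unpenalized fit is declared separated
_SEPARATION_BOUND = 40.0


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate of a survival function.

    ``event_times`` are the sorted distinct observation times (with 0
    prepended), ``survival_prob`` the estimate at each time, and
    ``n_at_risk`` the risk-set size just before each time.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    @property
    def median(self) -> float:
        """Median survival time; ``inf`` when the curve never reaches 0.5."""
        below = np.nonzero(self.survival_prob <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else np.inf


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def _as_survival_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of overall survival.

    Censored-only input yields a flat curve at 1.
    """
    t, e = _as_survival_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[float(t.size)], at_risk])
    return SurvivalCurve(grid, surv, at_risk)


def logrank_test(times, events, group) -> LogRankResult:
    """k-sample log-rank test (chi-square, df = k-1).

    Labels are opaque; swapping them leaves the result unchanged. Requires
    every group non-empty and at least one observed event overall.
    """
    t, e = _as_survival_arrays(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group labels must match times in length")
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if e.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    res = multivariate_logrank_test(t, g, e)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):  # all groups identical in composition
        stat = 0.0
    df = int(labels.size - 1)
    p = float(sps.chi2.sf(stat, df))
    return LogRankResult(statistic=stat, df=df, p_value=p)


def wilcoxon_de_test(x, y, paired: bool = True) -> float:
    """Two-sided Wilcoxon p-value: signed-rank when paired, rank-sum otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal-length inputs")
        if np.all(x == y):
            raise ValueError("paired test undefined: all differences are zero")
        return float(sps.wilcoxon(x, y, alternative="two-sided").pvalue)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# logistic regression (batched Newton / IRLS)
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit (optionally ridge-penalized).

    ``aic`` is 2k - 2*loglik with the unpenalized log-likelihood evaluated
    at the estimate; ``converged`` reports whether the optimizer reached
    its tolerance, ``penalized`` whether the ridge fallback was engaged
    after separation.
    """

    gene_names: list[str]
    intercept: float
    coefficients: np.ndarray
    converged: bool
    penalized: bool
    ridge: float
    loglik: float
    aic: float
    predicted_prob: np.ndarray = field(repr=False)


def _newton_batch(Xb: np.ndarray, y: np.ndarray, ridge: float,
                  max_iter: int = 100, tol: float = 1e-6):
    """Newton-Raphson on a (B, p, n) stack of designs sharing response y.

    Row 0 of each design must be the intercept. ``ridge`` penalizes
    (lambda/2)*||beta||^2 excluding the intercept. Returns
    (beta, loglik, converged, separated); loglik is unpenalized.
    """
    B, p, n = Xb.shape
    beta = np.zeros((B, p))
    pen = np.full(p, ridge)
    pen[0] = 0.0
    converged = np.zeros(B, dtype=bool)
    separated = np.zeros(B, dtype=bool)
    active = np.arange(B)
    Xa, ba = Xb, beta
    diag = np.arange(p)
    for _ in range(max_iter):
        eta = np.matmul(ba[:, None, :], Xa)[:, 0, :]
        np.clip(eta, -35.0, 35.0, out=eta)
        mu = expit(eta)
        grad = np.matmul(Xa, (y[None, :] - mu)[:, :, None])[:, :, 0] - pen * ba
        done = np.max(np.abs(grad), axis=1) < tol
        blown = np.max(np.abs(ba), axis=1) > _SEPARATION_BOUND
        converged[active[done]] = True
        separated[active[blown & ~done]] = True
        beta[active] = ba
        keep = ~(done | blown)
        if not keep.any():
            break
        if not keep.all():  # shrink the working set in place
            active = active[keep]
            Xa, ba, mu, grad = Xa[keep], ba[keep], mu[keep], grad[keep]
        w = mu * (1.0 - mu) + 1e-12
        H = np.matmul(Xa * w[:, None, :], Xa.transpose(0, 2, 1))
        H[:, diag, diag] += pen + 1e-10
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            H[:, diag, diag] += 1e-6
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        ba = ba + step
    beta[active] = ba
    eta = np.matmul(beta[:, None, :], Xb)[:, 0, :]
    np.clip(eta, -35.0, 35.0, out=eta)
    loglik = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
    return beta, loglik, converged, separated


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response contains a single class")
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("response must be binary 0/1")


def fit_logistic_batch(X: np.ndarray, y, subsets: np.ndarray,
                       ridge: float = 0.0,
                       fallback_ridge: float = FALLBACK_RIDGE,
                       tol: float = 1e-6) -> dict:
    """Fit one logistic model per row of ``subsets`` (column indices into X).

    All models share the response ``y``. Models whose unpenalized fit
    separates or fails to converge are refit with ``fallback_ridge``.
    Returns a dict of arrays: beta (B, k+1), loglik, aic, auc,
    prob (B, n), converged, penalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    subsets = np.asarray(subsets, dtype=np.intp)
    if subsets.ndim != 2:
        raise ValueError("subsets must be a (B, k) index array")
    _validate_xy(X, y)
    B, k = subsets.shape
    n = X.shape[0]
    XT = np.ascontiguousarray(X.T)
    Xb = np.empty((B, k + 1, n))
    Xb[:, 0, :] = 1.0
    Xb[:, 1:, :] = XT[subsets]
    beta, ll, conv, sep = _newton_batch(Xb, y, ridge, tol=tol)
    penalized = np.zeros(B, dtype=bool)
    redo = np.nonzero(sep | ~conv)[0]
    if ridge == 0.0 and redo.size:
        b2, ll2, c2, _ = _newton_batch(Xb[redo], y, fallback_ridge, tol=tol)
        beta[redo], ll[redo], conv[redo] = b2, ll2, c2
        penalized[redo] = True
    eta = np.matmul(beta[:, None, :], Xb)[:, 0, :]
    np.clip(eta, -35.0, 35.0, out=eta)
    prob = expit(eta)
    return {
        "beta": beta,
        "loglik": ll,
        "aic": 2.0 * (k + 1) - 2.0 * ll,
        "auc": auc_batch(prob, y),
        "prob": prob,
        "converged": conv,
        "penalized": penalized,
    }


def fit_logistic(X, y, ridge: float = 0.0, gene_names: list[str] | None = None,
                 fallback_ridge: float = FALLBACK_RIDGE) -> LogisticModel:
    """Logistic MLE of P(dead | expression) with ridge fallback on separation."""
    if isinstance(X, pd.DataFrame):
        if gene_names is None:
            gene_names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if gene_names is None:
        gene_names = [f"x{i}" for i in range(X.shape[1])]
    _validate_xy(X, y)
    res = fit_logistic_batch(X, y, np.arange(X.shape[1])[None, :],
                             ridge=ridge, fallback_ridge=fallback_ridge,
                             tol=1e-10)
    beta = res["beta"][0]
    return LogisticModel(
        gene_names=list(gene_names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        converged=bool(res["converged"][0]),
        penalized=bool(res["penalized"][0]),
        ridge=float(fallback_ridge if res["penalized"][0] else ridge),
        loglik=float(res["loglik"][0]),
        aic=float(res["aic"][0]),
        predicted_prob=res["prob"][0].copy(),
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    variance: float
    n_pos: int
    n_neg: int


def auc_batch(scores: np.ndarray, labels) -> np.ndarray:
    """Mann-Whitney AUC (ties get 0.5 credit) for each row of ``scores``."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels, dtype=float)
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sps.rankdata(scores, axis=1)
    pos_rank_sum = ranks[:, pos].sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (v10 per positive, v01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, nn = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - sps.rankdata(pos)) / nn
    v01 = 1.0 - (all_ranks[m:] - sps.rankdata(neg)) / m
    return v10, v01


def auc(scores, labels) -> RocResult:
    """AUC with its DeLong variance estimate."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    v10, v01 = _delong_components(scores, y)
    var = 0.0
    if n_pos > 1:
        var += float(np.var(v10, ddof=1)) / n_pos
    if n_neg > 1:
        var += float(np.var(v01, ddof=1)) / n_neg
    return RocResult(auc=float(v10.mean()), variance=var,
                     n_pos=n_pos, n_neg=n_neg)


def delong_compare(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for the paired difference of two AUCs.

    Both score vectors must refer to the same samples and labels. Identical
    (or monotonically related) scores give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors and labels must share one length")
    if ((y == 1).sum() == 0) or ((y == 0).sum() == 0):
        raise ValueError("DeLong comparison requires both classes present")
    v10a, v01a = _delong_components(a, y)
    v10b, v01b = _delong_components(b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, nn = v10a.size, v01a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if nn > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / nn
    diff = auc_a - auc_b
    if var <= 1e-15:
        if abs(diff) < 1e-12:
            return 1.0
        raise ValueError(
            "degenerate DeLong variance with unequal AUCs "
            f"(diff={diff:.3g}); scores may be constant within class")
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))
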