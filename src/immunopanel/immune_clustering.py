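"""Patient stratification from immune-cell fraction profiles.

Three operations reproduce the infiltration arm of the discovery
procedure: a Gaussian-mixture clustering of samples in immune-composition
space (groups selected by BIC, or with a fixed number of components), the
cumulative-SD high/low cutoff used to dichotomize a long-tailed
infiltration variable, and a per-cell-type survival screen that combines
the cutoff with a log-rank test.

The cumulative-SD rule: sort the samples (descending by default, so the
accumulating prefix starts in the long right tail), compute the standard
deviation of the first 3, first 4, ... samples, and cut where the prefix
SD is maximal. The trace of prefix SDs is kept on the result so the
chosen rank can be audited; the argmax is restricted so both groups keep
at least three samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .stats import LogRankResult, SurvivalCurve, km_estimate, logrank_test

__all__ = [
    "GmmFit",
    "StratifiedGroups",
    "fit_gmm",
    "cumulative_sd_cutoff",
    "celltype_survival_screen",
    "cluster_survival",
]


@dataclass
class GmmFit:
    """A fitted Gaussian mixture over samples.

    ``responsibilities`` is samples-by-k (rows sum to 1); ``assignment``
    the argmax hard label per sample. ``bic_by_k`` records the model
    selection trace.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: pd.DataFrame = field(repr=False)
    assignment: pd.Series = field(repr=False)
    bic: float
    loglik: float
    seed: int
    bic_by_k: dict[int, float]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment.index)


def fit_gmm(features: pd.DataFrame, k_range=range(2, 9), n_init: int = 10,
            seed: int = 0, covariance_type: str = "diag",
            reg_covar: float = 1e-6) -> GmmFit:
    """Best-BIC Gaussian mixture over ``k_range`` with multiple restarts.

    ``features`` is samples-by-dimensions. Deterministic given ``seed``.
    The default diagonal covariance keeps the per-component parameter
    count proportionate to typical cohort sizes (a full covariance in 22
    dimensions costs 253 parameters per component and drives BIC toward
    too few components at n of a few hundred); pass
    ``covariance_type="full"`` for unconstrained components.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    if ks[-1] >= X.shape[0]:
        raise ValueError(
            f"largest k ({ks[-1]}) must be below the sample count ({X.shape[0]})")
    best = None
    bic_by_k: dict[int, float] = {}
    for k in ks:
        gm = GaussianMixture(n_components=k, covariance_type=covariance_type,
                             n_init=n_init, reg_covar=reg_covar,
                             random_state=seed)
        gm.fit(X)
        bic = float(gm.bic(X))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    resp = gm.predict_proba(X)
    return GmmFit(
        k=k,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        responsibilities=pd.DataFrame(resp, index=features.index,
                                      columns=list(range(k))),
        assignment=pd.Series(resp.argmax(axis=1), index=features.index,
                             name="cluster"),
        bic=bic,
        loglik=float(gm.score(X) * X.shape[0]),
        seed=seed,
        bic_by_k=bic_by_k,
    )


@dataclass
class StratifiedGroups:
    """High/low dichotomy of one variable by the cumulative-SD rule.

    ``sorted_order`` lists sample IDs in the sort order used;
    ``cutoff_rank`` is the 1-based prefix length whose SD is maximal
    (the "high" group is the first ``cutoff_rank`` samples);
    ``sd_trace[j]`` is the SD of the first ``3 + j`` samples, for prefixes
    3..n (length n - 2).
    """

    variable_name: str
    sorted_order: list
    cutoff_rank: int
    cutoff_value: float
    group_label: pd.Series = field(repr=False)
    sd_trace: np.ndarray = field(repr=False)


def cumulative_sd_cutoff(values, descending: bool = True,
                         rule: str = "max_increase",
                         name: str | None = None) -> StratifiedGroups:
    """Split samples into high/low groups from the cumulative-SD curve.

    ``values`` may be a pandas Series (IDs taken from the index) or an
    array (positional IDs). Samples are sorted (descending by default),
    prefix SDs are computed for prefixes of length 3..n, and the cutoff
    is chosen within prefix lengths 3..n-3 (first maximum on ties), so
    both groups keep at least three samples.

    ``rule="max_increase"`` (default) cuts where the curve takes its
    largest single-step rise: the prefix SD of sorted data is small while
    the prefix stays inside the homogeneous extreme group and jumps when
    the first bulk sample is absorbed, so the largest rise marks the
    boundary of the extreme group. ``rule="max_sd"`` cuts at the literal
    maximum of the curve; note that for a two-component mixture the
    prefix SD keeps rising until the components are balanced, so this
    variant tends to overshoot a planted boundary and is provided for
    comparison only. Requires n >= 6 and non-constant input.
    """
    if isinstance(values, pd.Series):
        series = values.astype(float)
    else:
        arr = np.asarray(values, dtype=float)
        series = pd.Series(arr, index=pd.RangeIndex(arr.size))
    if name is None:
        name = str(series.name) if series.name is not None else "value"
    n = series.size
    if n < 6:
        raise ValueError(f"cumulative SD cutoff needs n >= 6 (got {n})")
    if series.nunique() == 1:
        raise ValueError("cumulative SD cutoff undefined for constant input")
    order = series.sort_values(ascending=not descending, kind="stable")
    x = order.to_numpy()
    # prefix SDs for k = 3..n via streaming moments
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    ks = np.arange(3, n + 1)
    var = (csq[2:] - csum[2:] ** 2 / ks) / (ks - 1)
    sd_trace = np.sqrt(np.maximum(var, 0.0))
    n_eligible = n - 5  # prefixes 3..n-3 may host the cutoff
    if rule == "max_increase":
        rises = np.diff(sd_trace)  # rise from prefix k to k+1, k = 3..n-1
        cutoff_rank = int(np.argmax(rises[:n_eligible]) + 3)
    elif rule == "max_sd":
        cutoff_rank = int(np.argmax(sd_trace[:n_eligible]) + 3)
    else:
        raise ValueError(f"unknown cutoff rule {rule!r}")
    labels = pd.Series("low", index=order.index, name=name)
    labels.iloc[:cutoff_rank] = "high"
    return StratifiedGroups(
        variable_name=name,
        sorted_order=list(order.index),
        cutoff_rank=cutoff_rank,
        cutoff_value=float(x[cutoff_rank - 1]),
        group_label=labels.reindex(series.index),
        sd_trace=sd_trace,
    )


def _survival_frame(clinical: pd.DataFrame, sample_ids) -> pd.DataFrame:
    missing = [s for s in sample_ids if s not in clinical.index]
    if missing:
        raise ValueError(f"clinical table missing samples: {missing[:5]}...")
    sub = clinical.loc[list(sample_ids)]
    return sub[["os_time_days", "os_event"]].astype(float)


def celltype_survival_screen(fractions: pd.DataFrame, clinical: pd.DataFrame,
                             min_group: int = 10, zero_threshold: float = 1e-4,
                             zero_proportion: float = 0.9) -> pd.DataFrame:
    """Screen every cell type for survival association after dichotomization.

    For each cell type: apply the cumulative-SD cutoff to its fractions,
    then a two-group log-rank test. Cell types with insufficient data are
    reported with status ``excluded`` rather than raising: a cell type is
    excluded when more than ``zero_proportion`` of samples fall below
    ``zero_threshold`` or when either stratum ends up smaller than
    ``min_group``. ``direction`` is +1 when the high-infiltration group
    has the longer median survival, -1 when shorter (adverse).
    """
    surv = _survival_frame(clinical, fractions.index)
    rows = []
    for ct in fractions.columns:
        vals = fractions[ct]
        rec: dict = {"celltype": ct, "status": "ok", "p_value": np.nan,
                     "statistic": np.nan, "direction": 0,
                     "cutoff_rank": np.nan, "n_high": 0, "n_low": 0}
        if (vals < zero_threshold).mean() > zero_proportion:
            rec["status"] = "excluded"
            rec["reason"] = "mostly-zero fractions"
            rows.append(rec)
            continue
        try:
            strat = cumulative_sd_cutoff(vals, name=ct)
        except ValueError as exc:
            rec["status"] = "excluded"
            rec["reason"] = str(exc)
            rows.append(rec)
            continue
        labels = strat.group_label
        n_high = int((labels == "high").sum())
        n_low = int((labels == "low").sum())
        rec.update(cutoff_rank=strat.cutoff_rank, n_high=n_high, n_low=n_low)
        if min(n_high, n_low) < min_group:
            rec["status"] = "excluded"
            rec["reason"] = f"stratum below min_group={min_group}"
            rows.append(rec)
            continue
        try:
            lr = logrank_test(surv["os_time_days"], surv["os_event"],
                              (labels == "high").astype(int))
        except ValueError as exc:
            rec["status"] = "excluded"
            rec["reason"] = str(exc)
            rows.append(rec)
            continue
        med_high = km_estimate(
            surv.loc[labels == "high", "os_time_days"],
            surv.loc[labels == "high", "os_event"]).median
        med_low = km_estimate(
            surv.loc[labels == "low", "os_time_days"],
            surv.loc[labels == "low", "os_event"]).median
        if med_high == med_low:
            direction = 0
        else:
            direction = 1 if med_high > med_low else -1
        rec.update(p_value=lr.p_value, statistic=lr.statistic,
                   direction=direction, reason="")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("celltype")


def cluster_survival(fit: GmmFit, clinical: pd.DataFrame
                     ) -> tuple[LogRankResult, dict[int, SurvivalCurve]]:
    """k-sample log-rank across GMM clusters plus per-cluster KM curves.

    Clusters that received no samples are dropped with a warning; a
    single-cluster fit cannot be compared and raises.
    """
    assignment = fit.assignment
    surv = _survival_frame(clinical, assignment.index)
    present = sorted(assignment.unique())
    empty = sorted(set(range(fit.k)) - set(present))
    if empty:
        warnings.warn(f"clusters with no assigned samples dropped: {empty}",
                      stacklevel=2)
    if len(present) < 2:
        raise ValueError("cluster survival comparison needs >= 2 non-empty clusters")
    result = logrank_test(surv["os_time_days"], surv["os_event"],
                          assignment.to_numpy())
    curves = {
        int(c): km_estimate(surv.loc[assignment == c, "os_time_days"],
                            surv.loc[assignment == c, "os_event"])
        for c in present
    }
    return result, curves
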