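"""The immune gene index: fold change x mean tumor expression.

For the poor-survival cohort, each gene receives an index equal to its
mean tumor expression (linear FPKM scale) multiplied by its tumor versus
adjacent-normal fold change. Genes are ranked by descending index; the
candidate shortlist is cut at the last pronounced drop in the ranked
index values. A tertile expression screen (top third versus bottom
third) with a log-rank test and single-gene ROC completes the module.

Fold changes are ratios of group means on the linear scale with a small
pseudocount guard; on this scale an abundant, strongly upregulated gene
reaches an index of several thousand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import LogRankResult, RocResult, auc, logrank_test

__all__ = [
    "fold_change",
    "immune_gene_index",
    "rank_by_index",
    "select_top_by_drop",
    "tertile_screen",
]


def fold_change(tumor: pd.DataFrame, normal: pd.DataFrame,
                pseudocount: float = 0.01) -> pd.Series:
    """Per-gene linear fold change (mean tumor + pc) / (mean normal + pc).

    Matrices are genes-by-samples and are aligned on their gene index;
    sharing no genes is an error. The pseudocount keeps genes absent from
    normal tissue finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    shared = tumor.index.intersection(normal.index)
    if shared.empty:
        raise ValueError("tumor and normal matrices share no genes")
    mt = tumor.loc[shared].mean(axis=1)
    mn = normal.loc[shared].mean(axis=1)
    fc = (mt + pseudocount) / (mn + pseudocount)
    fc.name = "fold_change"
    return fc


def immune_gene_index(mean_expr, fc):
    """index = mean tumor expression x fold change (element-wise).

    Accepts scalars or aligned vectors; inputs must be non-negative.
    Display rounding to 2 decimals is left to the caller.
    """
    me = np.asarray(mean_expr, dtype=float)
    f = np.asarray(fc, dtype=float)
    if np.any(me < 0) or np.any(f < 0):
        raise ValueError("index inputs must be non-negative")
    out = me * f
    if np.isscalar(mean_expr) or out.ndim == 0:
        return float(out)
    if isinstance(mean_expr, pd.Series):
        return pd.Series(out, index=mean_expr.index, name="index")
    return out


def rank_by_index(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by descending index; ties broken alphabetically by symbol.

    ``table`` needs columns ``gene``, ``mean_tumor_expr``, ``fold_change``
    (``index`` is recomputed). Returns a copy sorted by rank with a
    1-based ``rank`` column.
    """
    if table.empty:
        raise ValueError("cannot rank an empty table")
    out = table.copy()
    out["gene"] = out["gene"].astype(str).str.upper()
    out["index"] = immune_gene_index(out["mean_tumor_expr"].to_numpy(),
                                     out["fold_change"].to_numpy())
    out = out.sort_values(["index", "gene"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_top_by_drop(table: pd.DataFrame, max_k: int = 10,
                       drop_ratio: float = 1.3) -> dict:
    """Cut the ranked index list at the last pronounced drop.

    Scanning ranks 1..max_k of the ranked table, the shortlist length k is
    the LAST rank whose index exceeds the next index by at least
    ``drop_ratio`` (consecutive ratio >= drop_ratio); if no rank
    qualifies, k falls back to ``max_k``. The applied rule and parameters
    are recorded in the result for auditability.
    """
    if drop_ratio <= 1.0:
        raise ValueError("drop_ratio must exceed 1")
    ranked = table if "rank" in table.columns else rank_by_index(table)
    if len(ranked) < max_k + 1:
        raise ValueError(f"table needs more than max_k={max_k} rows")
    idx = ranked["index"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = idx[:max_k] / idx[1: max_k + 1]
    qualifying = np.nonzero(ratios >= drop_ratio)[0]
    if qualifying.size:
        k = int(qualifying[-1] + 1)
        rule = "last consecutive-index ratio >= drop_ratio"
    else:
        k = max_k
        rule = "fallback: no ratio >= drop_ratio within max_k"
    return {
        "genes": list(ranked["gene"].iloc[:k]),
        "k": k,
        "rule": rule,
        "drop_ratio": drop_ratio,
        "max_k": max_k,
        "ratios": ratios,
    }


@dataclass(frozen=True)
class TertileScreenResult:
    groups: pd.Series
    logrank: LogRankResult
    roc: RocResult


def tertile_screen(expr_values: pd.Series, clinical: pd.DataFrame
                   ) -> TertileScreenResult:
    """Top-third vs bottom-third expression split with survival and ROC.

    The middle tertile is excluded from the log-rank comparison; the ROC
    uses the raw expression of all samples against vital status. Group
    size is ceil(n/3); boundary ties are resolved by stable sort order.
    """
    vals = expr_values.astype(float)
    n = vals.size
    if n < 9:
        raise ValueError(f"tertile screen needs n >= 9 (got {n})")
    if vals.nunique() < 3:
        raise ValueError("too few distinct expression values for tertiles")
    surv = clinical.loc[vals.index, ["os_time_days", "os_event"]].astype(float)
    g = int(np.ceil(n / 3))
    order = vals.sort_values(ascending=False, kind="stable")
    groups = pd.Series(pd.NA, index=vals.index, dtype="object", name="tertile")
    groups.loc[order.index[:g]] = "high"
    groups.loc[order.index[-g:]] = "low"
    mask = groups.notna()
    lr = logrank_test(surv.loc[mask, "os_time_days"],
                      surv.loc[mask, "os_event"],
                      (groups[mask] == "high").astype(int).to_numpy())
    roc = auc(vals.to_numpy(), surv["os_event"].to_numpy())
    return TertileScreenResult(groups=groups, logrank=lr, roc=roc)
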