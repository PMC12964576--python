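"""Multi-stage prognostic panel construction.

Stages, in order: paired Wilcoxon differential expression (upregulated in
tumor), a cell-type expression filter against an immune-cell annotation
table, bidirectional AIC stepwise logistic selection, Monte-Carlo
benchmarking of random k-gene combinations against positive- and
negative-control pools, frequency profiling of genes in high-performing
combinations, exhaustive search over all subsets of the top genes, and
leave-one-gene-out attribution for the winning panel.

All logistic fits go through the batched Newton solver in
:mod:`immunopanel.stats`; AUCs are in-sample (the model is fit and
evaluated on the same cohort), which matches the discovery procedure
being reproduced but is optimistic — reports label them accordingly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import LogisticModel, fit_logistic, fit_logistic_batch

__all__ = [
    "CelltypeAnnotation",
    "CombinationBenchmarkResult",
    "FrequencyProfile",
    "PanelSearchResult",
    "differential_upregulated",
    "filter_by_celltype_expression",
    "stepwise_select",
    "benchmark_random_combinations",
    "frequency_profile",
    "exhaustive_panel_search",
    "leave_one_out",
]

_EXHAUSTIVE_CAP = 20
_BATCH = 1024


# ---------------------------------------------------------------------------
# differential expression and annotation filter
# ---------------------------------------------------------------------------


def differential_upregulated(tumor: pd.DataFrame, normal: pd.DataFrame,
                             pairing: Sequence[tuple[str, str]] | None = None,
                             alpha: float = 0.05,
                             fdr: bool = False) -> tuple[list[str], pd.DataFrame]:
    """Genes upregulated in tumor by a paired two-sided Wilcoxon test.

    ``pairing`` lists (tumor_sample, normal_sample) matched pairs; when
    omitted, columns are matched by position (requires equal counts). A
    gene qualifies when its signed-rank p-value is below ``alpha`` AND its
    mean tumor expression exceeds its mean normal expression. P-values are
    raw by default; ``fdr=True`` applies Benjamini-Hochberg instead.

    Returns the qualifying gene list and the full per-gene table.
    """
    if pairing is None:
        if tumor.shape[1] != normal.shape[1]:
            raise ValueError("without pairing, tumor and normal need equal "
                             "sample counts")
        pairing = list(zip(tumor.columns, normal.columns))
    if len(pairing) < 6:
        raise ValueError("paired differential expression needs >= 6 pairs")
    t_cols = [p[0] for p in pairing]
    n_cols = [p[1] for p in pairing]
    shared = tumor.index.intersection(normal.index)
    if shared.empty:
        raise ValueError("tumor and normal matrices share no genes")
    T = tumor.loc[shared, t_cols].to_numpy(dtype=float)
    N = normal.loc[shared, n_cols].to_numpy(dtype=float)
    diffs = T - N
    nonzero = (diffs != 0).any(axis=1)
    pvals = np.full(shared.size, np.nan)
    if nonzero.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.wilcoxon(T[nonzero], N[nonzero], axis=1,
                               alternative="two-sided")
        pvals[nonzero] = np.asarray(res.pvalue, dtype=float)
    table = pd.DataFrame({
        "gene": shared,
        "mean_tumor": T.mean(axis=1),
        "mean_normal": N.mean(axis=1),
        "p_value": pvals,
    }).set_index("gene")
    p_used = table["p_value"].copy()
    if fdr:
        ok = p_used.notna()
        p_used.loc[ok] = sps.false_discovery_control(p_used[ok])
    table["p_adjusted" if fdr else "p_raw"] = p_used
    up = (p_used < alpha) & (table["mean_tumor"] > table["mean_normal"])
    table["upregulated"] = up.fillna(False)
    genes = sorted(table.index[table["upregulated"]])
    return genes, table


@dataclass(frozen=True)
class CelltypeAnnotation:
    """Gene -> immune cell types in which the gene is expressed."""

    mapping: Mapping[str, frozenset[str]]
    vocabulary: frozenset[str] = frozenset()

    def __post_init__(self):
        vocab = set(self.vocabulary)
        for types in self.mapping.values():
            vocab |= set(types)
        object.__setattr__(self, "vocabulary", frozenset(vocab))

    def types_for(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())


def filter_by_celltype_expression(genes: Sequence[str],
                                  annotation: CelltypeAnnotation | Mapping,
                                  required_celltypes: Sequence[str],
                                  ) -> tuple[list[str], dict[str, list[str]]]:
    """Keep genes expressed in at least one of the required cell types.

    Unannotated genes are dropped and reported. Returns (kept, report)
    where report maps drop reasons to gene lists.
    """
    if not isinstance(annotation, CelltypeAnnotation):
        annotation = CelltypeAnnotation(mapping={
            g: frozenset(v) for g, v in dict(annotation).items()})
    required = set(required_celltypes)
    if not required:
        raise ValueError("required_celltypes must be non-empty")
    unknown = required - set(annotation.vocabulary)
    if unknown:
        raise ValueError(f"required cell types outside the annotation "
                         f"vocabulary: {sorted(unknown)}")
    kept, unannotated, no_match = [], [], []
    for g in genes:
        types = annotation.types_for(g)
        if not types:
            unannotated.append(g)
        elif types & required:
            kept.append(g)
        else:
            no_match.append(g)
    return kept, {"unannotated": unannotated, "no_required_celltype": no_match}


# ---------------------------------------------------------------------------
# stepwise logistic selection
# ---------------------------------------------------------------------------


def stepwise_select(X: pd.DataFrame, y, criterion: str = "aic",
                    max_steps: int = 100, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> list[str]:
    """Bidirectional stepwise logistic selection from the null model.

    At each step every single add/remove move is evaluated (moves of equal
    size are fit in one batch) and the move that most improves the
    criterion is applied; the search stops when no move improves or
    ``max_steps`` is reached. With ``criterion="aic"`` improvement means
    lower AIC; with ``criterion="pvalue"`` forward moves need a
    likelihood-ratio p below ``p_enter`` and backward moves fire when a
    variable's LR p exceeds ``p_remove``. Deterministic: candidate ties
    resolve alphabetically. Moves whose fit fails to converge are skipped
    with a warning.
    """
    if criterion not in ("aic", "pvalue"):
        raise ValueError("criterion must be 'aic' or 'pvalue'")
    cols = sorted(str(c) for c in X.columns)
    Xm = X[cols].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("response contains a single class")
    col_idx = {c: i for i, c in enumerate(cols)}

    def batch_ll(subsets: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(subsets, dtype=np.intp)
        res = fit_logistic_batch(Xm, y, arr)
        return res["loglik"], res["converged"] | res["penalized"]

    # null model log-likelihood
    p1 = y.mean()
    ll_null = float(y.sum() * np.log(p1) + (y.size - y.sum()) * np.log(1 - p1))
    selected: list[str] = []
    ll_cur = ll_null
    aic_cur = 2.0 - 2.0 * ll_null
    for _ in range(max_steps):
        moves: list[tuple[str, str, float, float]] = []  # (kind, gene, ll, aic)
        add_cands = [c for c in cols if c not in selected]
        if add_cands:
            subs = [[col_idx[g] for g in selected] + [col_idx[c]]
                    for c in add_cands]
            lls, ok = batch_ll(subs)
            skipped = [c for c, o in zip(add_cands, ok) if not o]
            if skipped:
                warnings.warn(f"stepwise: skipped non-convergent add moves "
                              f"({len(skipped)} genes)", stacklevel=2)
            k = len(selected) + 2
            moves += [("add", c, float(ll), 2.0 * k - 2.0 * float(ll))
                      for c, ll, o in zip(add_cands, lls, ok) if o]
        if len(selected) >= 1:
            subs = [[col_idx[g] for g in selected if g != c] for c in selected]
            if selected and len(selected) == 1:
                rem_lls = np.array([ll_null])
                rem_ok = np.array([True])
            else:
                rem_lls, rem_ok = batch_ll(subs)
            k = len(selected)  # parameters incl intercept after removal
            moves += [("remove", c, float(ll), 2.0 * k - 2.0 * float(ll))
                      for c, ll, o in zip(selected, rem_lls, rem_ok) if o]
        if not moves:
            break
        if criterion == "aic":
            best = min(moves, key=lambda m: (m[3], m[0], m[1]))
            if best[3] >= aic_cur - 1e-9:
                break
        else:
            best = None
            # backward first: remove the least useful variable if its LR p
            # exceeds p_remove
            removals = [m for m in moves if m[0] == "remove"]
            if removals:
                worst = max(removals, key=lambda m: (m[2], m[1]))
                lr_p = sps.chi2.sf(2.0 * (ll_cur - worst[2]), 1)
                if lr_p > p_remove:
                    best = worst
            if best is None:
                adds = [m for m in moves if m[0] == "add"]
                if adds:
                    cand = max(adds, key=lambda m: (m[2], m[1]))
                    lr_p = sps.chi2.sf(2.0 * (cand[2] - ll_cur), 1)
                    if lr_p < p_enter:
                        best = cand
            if best is None:
                break
        kind, gene, ll, aic_new = best
        if kind == "add":
            selected.append(gene)
        else:
            selected.remove(gene)
        selected.sort()
        ll_cur, aic_cur = ll, aic_new
    return selected


# ---------------------------------------------------------------------------
# random-combination benchmarking
# ---------------------------------------------------------------------------


@dataclass
class CombinationBenchmarkResult:
    """AUC distribution of random k-gene logistic models from one pool."""

    pool_name: str
    pool_genes: list[str]
    k: int
    n_draws: int
    auc_values: np.ndarray = field(repr=False)
    combos: np.ndarray = field(repr=False)  # (n_draws, k) indices into pool
    seed: int = 0

    def combo_genes(self, i: int) -> list[str]:
        return [self.pool_genes[j] for j in self.combos[i]]


def _subset_auc(X: np.ndarray, y: np.ndarray, subsets: np.ndarray,
                batch: int = _BATCH) -> np.ndarray:
    out = np.empty(subsets.shape[0])
    for lo in range(0, subsets.shape[0], batch):
        res = fit_logistic_batch(X, y, subsets[lo: lo + batch])
        out[lo: lo + batch] = res["auc"]
    return out


def benchmark_random_combinations(pool: Sequence[str], k: int, n_draws: int,
                                  X: pd.DataFrame, y, seed: int = 0,
                                  pool_name: str = "pool",
                                  ) -> CombinationBenchmarkResult:
    """In-sample AUC of ``n_draws`` random k-gene logistic models.

    Each draw is a uniform k-subset of ``pool`` without replacement within
    the draw (repeats across draws allowed). ``X`` is samples-by-genes and
    must contain every pool gene; ``y`` is the binary vital status.
    Reproducible given ``seed``.
    """
    pool = list(dict.fromkeys(pool))
    if k < 1:
        raise ValueError("combination size k must be >= 1")
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} genes cannot supply "
                         f"{k}-gene combinations")
    missing = [g for g in pool if g not in X.columns]
    if missing:
        raise ValueError(f"pool genes absent from X: {missing[:5]}...")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_draws, len(pool)))
    combos = np.argsort(keys, axis=1)[:, :k].astype(np.intp)
    combos.sort(axis=1)
    Xp = X[pool].to_numpy(dtype=float)
    aucs = _subset_auc(Xp, np.asarray(y, dtype=float), combos)
    return CombinationBenchmarkResult(
        pool_name=pool_name, pool_genes=pool, k=k, n_draws=n_draws,
        auc_values=aucs, combos=combos, seed=seed)


@dataclass
class FrequencyProfile:
    """Per-gene appearance counts among combinations above an AUC threshold."""

    threshold: float
    counts: pd.Series = field(repr=False)
    mean_auc: pd.Series = field(repr=False)
    top: list[str] = field(default_factory=list)
    n_qualifying: int = 0


def frequency_profile(bench: CombinationBenchmarkResult, threshold: float,
                      top_m: int = 20) -> FrequencyProfile:
    """Rank pool genes by frequency in combinations with AUC > threshold.

    Ties in count are broken by the mean AUC of the combinations
    containing the gene, then alphabetically. Raises when no combination
    clears the threshold.
    """
    qual = bench.auc_values > threshold
    n_q = int(qual.sum())
    if n_q == 0:
        raise ValueError(
            f"no combination exceeds AUC threshold {threshold:.4f} "
            f"(max observed {bench.auc_values.max():.4f}); lower the threshold")
    flat = bench.combos[qual].ravel()
    counts = np.bincount(flat, minlength=len(bench.pool_genes))
    auc_rep = np.repeat(bench.auc_values[qual], bench.k)
    sums = np.bincount(flat, weights=auc_rep, minlength=len(bench.pool_genes))
    with np.errstate(invalid="ignore"):
        mean_auc = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    tbl = pd.DataFrame({
        "gene": bench.pool_genes,
        "count": counts,
        "mean_auc": mean_auc,
    }).sort_values(["count", "mean_auc", "gene"],
                   ascending=[False, False, True], kind="stable")
    top = list(tbl["gene"].iloc[:top_m])
    return FrequencyProfile(
        threshold=threshold,
        counts=pd.Series(counts, index=bench.pool_genes, name="count"),
        mean_auc=pd.Series(mean_auc, index=bench.pool_genes, name="mean_auc"),
        top=top,
        n_qualifying=n_q,
    )


# ---------------------------------------------------------------------------
# exhaustive search and attribution
# ---------------------------------------------------------------------------


@dataclass
class PanelSearchResult:
    best_subset: list[str]
    best_auc: float
    n_subsets_evaluated: int
    leave_one_out: pd.DataFrame = field(repr=False)
    model: LogisticModel = field(repr=False)


def exhaustive_panel_search(genes: Sequence[str], X: pd.DataFrame, y,
                            ) -> PanelSearchResult:
    """Evaluate every non-empty subset of ``genes`` by in-sample logistic AUC.

    Hard-capped at 20 genes (2^20 - 1 = 1,048,575 subsets). The winner is
    the maximum-AUC subset; exact AUC ties resolve to the smaller subset,
    then alphabetically. Leave-one-out attribution is computed for the
    winning subset.
    """
    genes = sorted(dict.fromkeys(str(g) for g in genes))
    m = len(genes)
    if m < 1:
        raise ValueError("need at least one candidate gene")
    if m > _EXHAUSTIVE_CAP:
        raise ValueError(f"exhaustive search capped at {_EXHAUSTIVE_CAP} genes "
                         f"(got {m})")
    Xp = X[genes].to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    best_auc = -np.inf
    best: tuple[int, tuple[str, ...]] | None = None
    n_eval = 0
    for size in range(1, m + 1):
        combos = np.array(list(itertools.combinations(range(m), size)),
                          dtype=np.intp)
        aucs = _subset_auc(Xp, yv, combos)
        n_eval += combos.shape[0]
        order = np.argsort(-aucs, kind="stable")
        top_i = order[0]
        cand_auc = float(aucs[top_i])
        # within a size, equal AUCs resolve alphabetically
        tied = np.nonzero(np.abs(aucs - cand_auc) <= 1e-12)[0]
        if tied.size > 1:
            names = [tuple(genes[j] for j in combos[t]) for t in tied]
            top_i = tied[int(np.argmin(np.array(names, dtype=object)))]
        cand_names = tuple(genes[j] for j in combos[top_i])
        if cand_auc > best_auc + 1e-12:
            best_auc, best = cand_auc, (size, cand_names)
        # smaller sizes were evaluated first, so an exact tie keeps the
        # earlier (smaller) subset
    subset = list(best[1])
    model = fit_logistic(X[subset], yv, gene_names=subset)
    loo = (leave_one_out(subset, X, yv, panel_auc=best_auc)
           if len(subset) >= 2 else
           pd.DataFrame(columns=["auc_without", "delta"]))
    return PanelSearchResult(
        best_subset=subset,
        best_auc=best_auc,
        n_subsets_evaluated=n_eval,
        leave_one_out=loo,
        model=model,
    )


def leave_one_out(panel: Sequence[str], X: pd.DataFrame, y,
                  panel_auc: float | None = None) -> pd.DataFrame:
    """Refit the panel without each gene; delta = panel AUC - reduced AUC.

    Genes are returned ranked by delta (largest contribution first).
    """
    panel = [str(g) for g in panel]
    if len(panel) < 2:
        raise ValueError("leave-one-out needs a panel of >= 2 genes")
    yv = np.asarray(y, dtype=float)
    Xp = X[panel].to_numpy(dtype=float)
    if panel_auc is None:
        full = fit_logistic_batch(Xp, yv, np.arange(len(panel))[None, :])
        panel_auc = float(full["auc"][0])
    subs = np.array([[j for j in range(len(panel)) if j != i]
                     for i in range(len(panel))], dtype=np.intp)
    aucs = _subset_auc(Xp, yv, subs)
    out = pd.DataFrame({
        "gene": panel,
        "auc_without": aucs,
        "delta": panel_auc - aucs,
    }).set_index("gene").sort_values("delta", ascending=False, kind="stable")
    return out
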