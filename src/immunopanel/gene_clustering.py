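"""Transcriptomic stratification on immune-regulatory gene expression.

Samples are clustered on the expression of a gene set (typically the
GO:0050776 "regulation of immune response" genes) and the poor-prognosis
strata of the expression view and the immune-infiltration view are
intersected to define the poor-survival discovery cohort.

Expression is z-scored per gene before clustering (raw FPKM scale would
let high-abundance genes dominate the Euclidean structure) and projected
onto leading principal components, since a full-covariance mixture in
hundreds of gene dimensions with a few hundred samples is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .immune_clustering import GmmFit, fit_gmm
from .stats import km_estimate, logrank_test

__all__ = [
    "GeneSet",
    "CohortDefinition",
    "subset_to_gene_set",
    "cluster_by_expression",
    "define_poor_survival_cohort",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols, uppercase-normalized and de-duplicated."""

    name: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self):
        norm = []
        seen = set()
        for s in self.gene_symbols:
            u = str(s).strip().upper()
            if u and u not in seen:
                seen.add(u)
                norm.append(u)
        if not norm:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "gene_symbols", tuple(norm))

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.gene_symbols)


def subset_to_gene_set(expr: pd.DataFrame, genes: GeneSet
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Restrict a genes-by-samples matrix to a gene set.

    Returns the subset (in gene-set order) and the symbols requested but
    absent from the matrix. An empty intersection raises.
    """
    index_upper = pd.Index([str(g).upper() for g in expr.index])
    lookup = {g: i for i, g in enumerate(index_upper)}
    present, missing = [], []
    for g in genes.gene_symbols:
        (present if g in lookup else missing).append(g)
    if not present:
        raise ValueError(
            f"gene set {genes.name!r} shares no genes with the matrix")
    sub = expr.iloc[[lookup[g] for g in present]]
    return sub, missing


def cluster_by_expression(expr: pd.DataFrame, k_range=range(2, 9),
                          seed: int = 0, n_init: int = 10,
                          n_components: int = 20,
                          standardize: bool = True) -> GmmFit:
    """GMM over samples in (standardized, PCA-reduced) expression space.

    ``expr`` is genes-by-samples. Genes with zero variance are dropped
    before standardization. Contract otherwise as :func:`fit_gmm`.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all genes have zero variance")
        X = (X[:, keep] - mu[keep]) / sd[keep]
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    if n_comp < X.shape[1]:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    feats = pd.DataFrame(X, index=expr.columns)
    return fit_gmm(feats, k_range=k_range, n_init=n_init, seed=seed)


@dataclass(frozen=True)
class CohortDefinition:
    """Poor-survival cohort as the intersection of two poor strata."""

    sample_ids: tuple[str, ...]
    source_immune_clusters: tuple[int, ...]
    source_gene_clusters: tuple[int, ...]
    rule: str = "intersection"
    empty: bool = False

    def __len__(self) -> int:
        return len(self.sample_ids)


def _median_by_cluster(assignment: pd.Series, surv: pd.DataFrame) -> pd.Series:
    """KM median survival per cluster; restricted mean as tie-resolver scale.

    Curves that never reach 0.5 get an infinite median; to keep the
    ordering usable when many curves are flat, infinite medians are
    ordered by restricted mean survival time (larger RMST = better).
    """
    med = {}
    for c in sorted(assignment.unique()):
        sub = surv.loc[assignment == c]
        curve = km_estimate(sub["os_time_days"], sub["os_event"])
        med[c] = curve.median
    return pd.Series(med)


def _restricted_mean(sub: pd.DataFrame, horizon: float) -> float:
    curve = km_estimate(sub["os_time_days"], sub["os_event"])
    t = np.append(curve.event_times, horizon)
    s = np.append(curve.survival_prob, curve.survival_prob[-1])
    widths = np.diff(np.clip(t, None, horizon))
    return float(np.sum(s[:-1] * widths))


def poor_clusters(fit: GmmFit, clinical: pd.DataFrame,
                  alpha: float = 0.05) -> list[int]:
    """Clusters with below-median survival that differ from the best cluster.

    A cluster is "poor" when its KM median survival is below the cohort
    median AND its pairwise log-rank test against the best-surviving
    cluster is significant at ``alpha``. When medians are unreached
    (curves stay above 0.5), restricted mean survival over the observed
    horizon takes the median's place in the ordering.
    """
    assignment = fit.assignment
    surv = clinical.loc[assignment.index, ["os_time_days", "os_event"]].astype(float)
    horizon = float(surv["os_time_days"].max())
    med = _median_by_cluster(assignment, surv)
    cohort_curve = km_estimate(surv["os_time_days"], surv["os_event"])
    cohort_med = cohort_curve.median
    if not np.isfinite(cohort_med) or not np.isfinite(med).all():
        # fall back to restricted means on the same scale
        med = pd.Series({
            c: _restricted_mean(surv.loc[assignment == c], horizon)
            for c in med.index})
        cohort_med = _restricted_mean(surv, horizon)
    best = med.idxmax()
    out = []
    for c in med.index:
        if c == best or not med[c] < cohort_med:
            continue
        pair = assignment.isin([c, best])
        lr = logrank_test(surv.loc[pair, "os_time_days"],
                          surv.loc[pair, "os_event"],
                          assignment[pair].to_numpy())
        if lr.p_value < alpha:
            out.append(int(c))
    return sorted(out)


def define_poor_survival_cohort(immune_fit: GmmFit, gene_fit: GmmFit,
                                clinical: pd.DataFrame,
                                alpha: float = 0.05) -> CohortDefinition:
    """Intersect the poor strata of the immune and expression clusterings.

    Both fits must cover the same sample universe. An empty intersection
    is a valid (flagged) result, not an error. The definition is invariant
    to cluster relabeling since clusters are selected by their survival
    behavior, not their labels.
    """
    ids_a = set(immune_fit.assignment.index)
    ids_b = set(gene_fit.assignment.index)
    if ids_a != ids_b:
        raise ValueError("immune and gene clusterings cover different samples")
    poor_immune = poor_clusters(immune_fit, clinical, alpha=alpha)
    poor_gene = poor_clusters(gene_fit, clinical, alpha=alpha)
    members_immune = set(
        immune_fit.assignment.index[immune_fit.assignment.isin(poor_immune)])
    members_gene = set(
        gene_fit.assignment.index[gene_fit.assignment.isin(poor_gene)])
    cohort = sorted(members_immune & members_gene)
    return CohortDefinition(
        sample_ids=tuple(cohort),
        source_immune_clusters=tuple(poor_immune),
        source_gene_clusters=tuple(poor_gene),
        empty=not cohort,
    )
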