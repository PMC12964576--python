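"""Panel construction stages: DE, filter, stepwise, benchmark, search, LOO."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from immunopanel.panel_selection import (CelltypeAnnotation,
                                         benchmark_random_combinations,
                                         differential_upregulated,
                                         exhaustive_panel_search,
                                         filter_by_celltype_expression,
                                         frequency_profile, leave_one_out,
                                         stepwise_select)
from immunopanel.synthetic import SyntheticCohortConfig, generate_cohort, \
    plant_separable_clusters


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def _paired_cohort(seed=0, n_pairs=38, n_genes=1000, n_de=50, fc=4.0):
    de = tuple((f"G{i:05d}", fc) for i in range(n_de))
    cfg = plant_separable_clusters(SyntheticCohortConfig(
        n_patients=n_pairs, n_genes=n_genes, de_spec=de, signal_spec=(),
        seed=seed))
    return generate_cohort(cfg), [g for g, _ in de]


def test_de_identical_matrices_yield_nothing(rng):
    expr = pd.DataFrame(rng.random((20, 8)) + 1,
                        index=[f"G{i}" for i in range(20)])
    genes, _ = differential_upregulated(expr, expr.copy())
    assert genes == []


def test_de_recovers_planted_upregulation():
    co, de_genes = _paired_cohort(seed=1)
    genes, table = differential_upregulated(co.tumor, co.normal)
    recall = len(set(genes) & set(de_genes)) / len(de_genes)
    nulls = table.index.difference(de_genes)
    fpr = table.loc[nulls, "upregulated"].mean()
    assert recall >= 0.9
    assert 0.01 <= fpr <= 0.09  # raw p at alpha=0.05, no correction


def test_de_direction_filter_excludes_downregulated():
    co, _ = _paired_cohort(seed=2, n_genes=100, n_de=5)
    tumor, normal = co.tumor.copy(), co.normal.copy()
    # make one planted gene downregulated by swapping tissue values
    tumor.loc["G00000"], normal.loc["G00000"] = (
        co.normal.loc["G00000"].to_numpy(), co.tumor.loc["G00000"].to_numpy())
    genes, table = differential_upregulated(tumor, normal)
    assert "G00000" not in genes
    assert table.loc["G00000", "p_value"] < 0.05


def test_de_requires_enough_pairs(rng):
    expr = pd.DataFrame(rng.random((5, 4)), index=list("ABCDE"))
    with pytest.raises(ValueError):
        differential_upregulated(expr, expr * 2)


# ---------------------------------------------------------------------------
# cell-type filter
# ---------------------------------------------------------------------------


def test_filter_set_arithmetic():
    genes = [f"G{i:03d}" for i in range(406)]
    mapping = {g: frozenset({"Macrophages M0"}) for g in genes[:372]}
    for g in genes[372:400]:
        mapping[g] = frozenset({"Eosinophils"})
    ann = CelltypeAnnotation(mapping=mapping,
                             vocabulary=frozenset({"Neutrophils"}))
    kept, report = filter_by_celltype_expression(
        genes, ann, ["Macrophages M0", "Neutrophils"])
    assert len(kept) == 372
    assert len(report["no_required_celltype"]) == 28
    assert len(report["unannotated"]) == 6


def test_filter_identity_and_empty():
    ann = CelltypeAnnotation(mapping={"A": frozenset({"T"}),
                                      "B": frozenset({"T"})})
    kept, _ = filter_by_celltype_expression(["A", "B"], ann, ["T"])
    assert kept == ["A", "B"]
    ann2 = CelltypeAnnotation(mapping={"A": frozenset({"U"})},
                              vocabulary=frozenset({"T", "U"}))
    kept2, report2 = filter_by_celltype_expression(["A", "B"], ann2, ["T"])
    assert kept2 == []
    with pytest.raises(ValueError):
        filter_by_celltype_expression(["A"], ann, [])


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


def _design_with_signal(rng, n=300, n_null=20, beta=1.2):
    X = rng.standard_normal((n, n_null + 1))
    names = [f"N{i:02d}" for i in range(n_null)] + ["SIGNAL"]
    y = (rng.random(n) < expit(beta * X[:, -1] - 0.3)).astype(float)
    return pd.DataFrame(X, columns=names), y


def test_stepwise_recovers_planted_gene():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y = _design_with_signal(rng)
        if "SIGNAL" in stepwise_select(X, y):
            hits += 1
    assert hits >= 8


def test_stepwise_null_selects_little():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.standard_normal((400, 15)),
                     columns=[f"N{i:02d}" for i in range(15)])
    y = (rng.random(400) < 0.5).astype(float)
    selected = stepwise_select(X, y)
    assert len(selected) <= 3  # AIC admits the occasional noise gene


def test_stepwise_duplicate_gene_selected_once():
    rng = np.random.default_rng(2)
    X, y = _design_with_signal(rng, n_null=5)
    X["SIGNAL_COPY"] = X["SIGNAL"]
    selected = stepwise_select(X, y)
    assert not ({"SIGNAL", "SIGNAL_COPY"} <= set(selected))


def test_stepwise_deterministic():
    rng = np.random.default_rng(3)
    X, y = _design_with_signal(rng)
    assert stepwise_select(X, y) == stepwise_select(X.copy(), y.copy())


# ---------------------------------------------------------------------------
# combination benchmarking
# ---------------------------------------------------------------------------


def test_benchmark_forced_combo_has_zero_variance(design300, y300):
    pool = list(design300.columns[:5])
    bench = benchmark_random_combinations(pool, k=5, n_draws=50,
                                          X=design300, y=y300, seed=0)
    assert np.ptp(bench.auc_values) == 0.0
    assert np.all(bench.combos == bench.combos[0])


def test_benchmark_reproducible_per_seed(design300, y300):
    pool = list(design300.columns[:30])
    a = benchmark_random_combinations(pool, k=10, n_draws=200,
                                      X=design300, y=y300, seed=9)
    b = benchmark_random_combinations(pool, k=10, n_draws=200,
                                      X=design300, y=y300, seed=9)
    assert np.array_equal(a.auc_values, b.auc_values)
    c = benchmark_random_combinations(pool, k=10, n_draws=200,
                                      X=design300, y=y300, seed=10)
    assert not np.array_equal(a.auc_values, c.auc_values)


def test_benchmark_signal_pool_beats_noise_pool(cohort300, design300, y300):
    signal = [g for g, b in cohort300.truth.signal_genes.items() if b >= 0.2]
    noise = [f"G{i:05d}" for i in range(1400, 1430)]
    bs = benchmark_random_combinations(signal, k=10, n_draws=300,
                                       X=design300, y=y300, seed=1)
    bn = benchmark_random_combinations(noise, k=10, n_draws=300,
                                       X=design300, y=y300, seed=1)
    assert bs.auc_values.mean() > bn.auc_values.mean()


def test_benchmark_pool_too_small_raises(design300, y300):
    with pytest.raises(ValueError):
        benchmark_random_combinations(list(design300.columns[:3]), k=5,
                                      n_draws=10, X=design300, y=y300)


# ---------------------------------------------------------------------------
# frequency profiling
# ---------------------------------------------------------------------------


def test_frequency_vacuous_threshold_matches_hypergeometric(design300, y300):
    pool = list(design300.columns[:40])
    bench = benchmark_random_combinations(pool, k=8, n_draws=2000,
                                          X=design300, y=y300, seed=4)
    prof = frequency_profile(bench, threshold=-1.0, top_m=10)
    expect = bench.n_draws * bench.k / len(pool)
    sd = np.sqrt(bench.n_draws * (bench.k / len(pool))
                 * (1 - bench.k / len(pool)))
    assert prof.n_qualifying == bench.n_draws
    assert np.all(np.abs(prof.counts.to_numpy() - expect) <= 3 * sd)


def test_frequency_threshold_above_max_raises(design300, y300):
    pool = list(design300.columns[:25])
    bench = benchmark_random_combinations(pool, k=5, n_draws=100,
                                          X=design300, y=y300, seed=5)
    with pytest.raises(ValueError, match="threshold"):
        frequency_profile(bench, threshold=1.5)


def test_frequency_counts_bounded_by_qualifying(design300, y300):
    pool = list(design300.columns[:25])
    bench = benchmark_random_combinations(pool, k=5, n_draws=500,
                                          X=design300, y=y300, seed=6)
    thr = float(np.quantile(bench.auc_values, 0.8))
    prof = frequency_profile(bench, threshold=thr, top_m=5)
    assert (prof.counts <= prof.n_qualifying).all()
    assert len(prof.top) == 5


# ---------------------------------------------------------------------------
# exhaustive search + leave-one-out
# ---------------------------------------------------------------------------


def brute_force_best_subset(genes, X, y):
    """Independent route: statsmodels MLE + sklearn AUC per subset."""
    best = None
    for size in range(1, len(genes) + 1):
        for combo in itertools.combinations(sorted(genes), size):
            design = sm.add_constant(X[list(combo)].to_numpy())
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            auc = roc_auc_score(y, fit.predict(design))
            key = (-auc, size, combo)
            if best is None or key < best[0]:
                best = (key, combo, auc)
    return list(best[1]), best[2]


def test_exhaustive_three_genes_matches_enumeration(design300, y300):
    genes = ["G00000", "G00001", "G01400"]
    res = exhaustive_panel_search(genes, design300, y300)
    want_subset, want_auc = brute_force_best_subset(genes, design300, y300)
    assert res.n_subsets_evaluated == 7
    assert res.best_subset == want_subset
    assert res.best_auc == pytest.approx(want_auc, abs=1e-6)


def test_exhaustive_perfect_predictor_reaches_ceiling(design300, y300):
    X = design300[["G00000", "G00001"]].copy()
    X["ORACLE"] = y300 + 0.001 * np.arange(len(y300))
    res = exhaustive_panel_search(["G00000", "G00001", "ORACLE"], X, y300)
    assert res.best_auc == 1.0
    assert "ORACLE" in res.best_subset


def test_exhaustive_beats_single_genes(design300, y300):
    genes = [f"G{i:05d}" for i in range(8)]
    res = exhaustive_panel_search(genes, design300, y300)
    singles = [exhaustive_panel_search([g], design300, y300).best_auc
               for g in genes[:3]]
    assert res.best_auc >= max(singles)


def test_exhaustive_cap(design300, y300):
    with pytest.raises(ValueError):
        exhaustive_panel_search([f"G{i:05d}" for i in range(21)],
                                design300, y300)


def test_leave_one_out_max_property(design300, y300):
    genes = [f"G{i:05d}" for i in range(10)]
    res = exhaustive_panel_search(genes, design300, y300)
    if len(res.best_subset) >= 2:
        assert (res.leave_one_out["auc_without"]
                <= res.best_auc + 1e-12).all()


def test_leave_one_out_redundant_gene_has_no_weight(design300, y300):
    X = design300[["G00000"]].copy()
    X["G00000_COPY"] = X["G00000"]
    loo = leave_one_out(["G00000", "G00000_COPY"], X, y300)
    assert np.allclose(loo["delta"], 0.0, atol=1e-9)


def test_leave_one_out_flags_dominant_gene(y300, design300):
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = design300[[f"G{i:05d}" for i in range(1400, 1404)]].copy()
        X["DOMINANT"] = y300 * 2 + rng.normal(0, 0.7, len(y300))
        loo = leave_one_out(list(X.columns), X, y300)
        if loo.index[0] == "DOMINANT":
            hits += 1
    assert hits >= 8
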