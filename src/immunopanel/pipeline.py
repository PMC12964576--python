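"""End-to-end orchestration of the poor-survival discovery pipeline.

Stage order mirrors the discovery procedure: immune-fraction clustering,
per-cell-type survival screen, immune-gene expression clustering,
poor-cohort intersection, gene index, differential expression, cell-type
filter + stepwise selection, combination benchmarking, frequency
profiling, exhaustive panel search with leave-one-out. Every stage writes
its artifact with the seed and parameters that produced it, and the run
manifest lists all outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as ipio
from .gene_clustering import (GeneSet, cluster_by_expression,
                              define_poor_survival_cohort, subset_to_gene_set)
from .gene_index import (fold_change, rank_by_index, select_top_by_drop,
                         tertile_screen)
from .immune_clustering import (celltype_survival_screen, cluster_survival,
                                fit_gmm)
from .panel_selection import (benchmark_random_combinations,
                              differential_upregulated,
                              exhaustive_panel_search,
                              filter_by_celltype_expression, frequency_profile,
                              stepwise_select)

logger = logging.getLogger("immunopanel")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    expression_tumor: str
    expression_normal: str
    fractions: str
    clinical: str
    immune_gene_set: str          # GMT; first set is used
    pc_pool: str                  # GMT positive-control pool
    nc_pool: str                  # GMT negative-control pool
    annotation: str               # gene -> cell types TSV
    outdir: str = "immunopanel_run"
    # stage parameters
    k_range: tuple[int, int] = (2, 8)
    fix_k: int | None = None      # fix the number of GMM clusters (e.g. 5)
    n_init: int = 10
    alpha: float = 0.05
    drop_ratio: float = 1.3
    index_max_k: int = 10
    combo_k: int = 20
    n_draws: int = 10_000
    threshold_mode: str = "pc_mean"   # or a float-convertible string
    top_m: int = 20
    min_group: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression_tumor", "expression_normal", "fractions",
                     "clinical", "immune_gene_set", "pc_pool", "nc_pool",
                     "annotation"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def ks(self) -> range:
        if self.fix_k is not None:
            return range(self.fix_k, self.fix_k + 1)
        return range(self.k_range[0], self.k_range[1] + 1)


def _tumor_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    return clinical[clinical["tissue"] == "tumor"]


def _pairing(clinical: pd.DataFrame, tumor_ids) -> list[tuple[str, str]]:
    """Matched (tumor, normal) sample pairs via the patient_id column."""
    by_patient: dict[str, dict[str, str]] = {}
    for sid, row in clinical.iterrows():
        by_patient.setdefault(row["patient_id"], {})[row["tissue"]] = sid
    pairs = []
    for sid in tumor_ids:
        patient = clinical.loc[sid, "patient_id"]
        tissues = by_patient.get(patient, {})
        if "tumor" in tissues and "normal" in tissues:
            pairs.append((tissues["tumor"], tissues["normal"]))
    return pairs


def _design(tumor: pd.DataFrame) -> pd.DataFrame:
    """Samples-by-genes logistic design: z-scored log1p expression."""
    X = np.log1p(tumor.to_numpy(dtype=float)).T
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((X - mu) / sd, index=tumor.columns, columns=tumor.index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "version": __version__}
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "params": dataclasses.asdict(config), "stages": []}
    manifest_path = outdir / "manifest.json"

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"].append({
            "name": stage,
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.monotonic() - t0, 3),
        })
        ipio.write_json(manifest, manifest_path)
        logger.info("stage %-18s done (%.1fs)", stage,
                    manifest["stages"][-1]["elapsed_s"])

    def run_stage(stage: str, fn):
        t0 = time.monotonic()
        try:
            outputs = fn()
        except Exception as exc:
            ipio.write_json(manifest, manifest_path)
            raise PipelineError(stage, exc) from exc
        record(stage, outputs, t0)

    # ---- load inputs ------------------------------------------------------
    tumor = ipio.read_expression(config.expression_tumor)
    normal = ipio.read_expression(config.expression_normal)
    fractions = ipio.read_fractions(config.fractions)
    clinical = ipio.read_clinical(config.clinical)
    immune_set = ipio.read_gmt(config.immune_gene_set)[0]
    pc_set = ipio.read_gmt(config.pc_pool)[0]
    nc_set = ipio.read_gmt(config.nc_pool)[0]
    annotation = ipio.read_celltype_annotation(config.annotation)
    tclin = _tumor_clinical(clinical)
    state: dict = {}

    # ---- stage 1: immune-fraction GMM ------------------------------------
    def stage_immune():
        fit = fit_gmm(fractions, k_range=config.ks(), n_init=config.n_init,
                      seed=config.seed)
        lr, _curves = (None, None)
        if fit.k >= 2:
            lr, _curves = cluster_survival(fit, clinical)
        state["immune_fit"] = fit
        out = outdir / "immune_clusters.tsv"
        ipio.write_table(fit.assignment.to_frame(), out,
                         meta={**meta, "k": fit.k, "bic": fit.bic,
                               "logrank_p": getattr(lr, "p_value", "NA")})
        return [out]

    run_stage("immune_clusters", stage_immune)

    # ---- stage 2: per-cell-type survival screen ---------------------------
    def stage_screen():
        screen = celltype_survival_screen(fractions, clinical,
                                          min_group=config.min_group)
        state["screen"] = screen
        out = outdir / "celltype_screen.tsv"
        ipio.write_table(screen, out, meta=meta)
        return [out]

    run_stage("celltype_screen", stage_screen)

    # ---- stage 3: immune-gene expression GMM ------------------------------
    def stage_gene_gmm():
        sub, missing = subset_to_gene_set(tumor, immune_set)
        fit = cluster_by_expression(sub, k_range=config.ks(),
                                    n_init=config.n_init, seed=config.seed)
        state["gene_fit"] = fit
        state["immune_expr"] = sub
        out = outdir / "gene_clusters.tsv"
        ipio.write_table(fit.assignment.to_frame(), out,
                         meta={**meta, "k": fit.k, "bic": fit.bic,
                               "missing_genes": len(missing)})
        return [out]

    run_stage("gene_clusters", stage_gene_gmm)

    # ---- stage 4: poor-survival cohort ------------------------------------
    def stage_cohort():
        cohort = define_poor_survival_cohort(state["immune_fit"],
                                             state["gene_fit"], clinical,
                                             alpha=config.alpha)
        state["cohort"] = cohort
        out = outdir / "poor_cohort.tsv"
        ipio.write_table(pd.DataFrame({"sample_id": cohort.sample_ids}), out,
                         meta={**meta,
                               "immune_clusters": cohort.source_immune_clusters,
                               "gene_clusters": cohort.source_gene_clusters,
                               "alpha": config.alpha}, index=False)
        if cohort.empty:
            logger.warning("poor-survival cohort is empty")
        return [out]

    run_stage("poor_cohort", stage_cohort)

    cohort_ids = list(state["cohort"].sample_ids)
    pairs = _pairing(clinical, cohort_ids)
    cohort_fallback = len(pairs) < 6
    if cohort_fallback:
        # the intersection can be legitimately empty/tiny; fall back to the
        # full matched cohort so the expression stages stay defined
        logger.warning(
            "poor-survival cohort has %d matched pairs (< 6); index and "
            "differential-expression stages fall back to all matched pairs",
            len(pairs))
        pairs = _pairing(clinical, list(tclin.index))
    design = _design(tumor)
    y = tclin.loc[design.index, "os_event"].to_numpy(dtype=float)

    # ---- stage 5: immune gene index ---------------------------------------
    def stage_index():
        t_cols = [p[0] for p in pairs]
        n_cols = [p[1] for p in pairs]
        sub = state["immune_expr"]
        fc = fold_change(sub[t_cols], normal.loc[sub.index, n_cols])
        table = pd.DataFrame({
            "gene": sub.index,
            "mean_tumor_expr": sub[t_cols].mean(axis=1).to_numpy(),
            "fold_change": fc.to_numpy(),
        })
        ranked = rank_by_index(table)
        top = select_top_by_drop(ranked, max_k=config.index_max_k,
                                 drop_ratio=config.drop_ratio)
        state["index_top"] = top
        screens = {}
        for gene in top["genes"]:
            try:
                res = tertile_screen(tumor.loc[gene, design.index], tclin)
                screens[gene] = {"logrank_p": res.logrank.p_value,
                                 "auc": res.roc.auc}
            except ValueError as exc:
                screens[gene] = {"error": str(exc)}
        out1 = outdir / "gene_index.tsv"
        out2 = outdir / "index_top_screen.json"
        ipio.write_table(ranked, out1,
                         meta={**meta, "n_pairs": len(pairs),
                               "cohort_fallback": cohort_fallback,
                               "drop_ratio": config.drop_ratio}, index=False)
        ipio.write_json({"top": top["genes"], "k": top["k"],
                         "rule": top["rule"], "screens": screens}, out2,
                        meta=meta)
        return [out1, out2]

    run_stage("gene_index", stage_index)

    # ---- stage 6: differential expression ---------------------------------
    def stage_de():
        sub = state["immune_expr"]
        genes, table = differential_upregulated(sub, normal.loc[sub.index],
                                                pairing=pairs,
                                                alpha=config.alpha)
        state["de_genes"] = genes
        out = outdir / "de_upregulated.tsv"
        ipio.write_table(table, out,
                         meta={**meta, "alpha": config.alpha,
                               "n_pairs": len(pairs),
                               "cohort_fallback": cohort_fallback,
                               "n_upregulated": len(genes)})
        return [out]

    run_stage("differential_expression", stage_de)

    # ---- stage 7: cell-type filter + stepwise selection -------------------
    def stage_stepwise():
        screen = state["screen"]
        sig = screen[(screen["status"] == "ok")
                     & (screen["p_value"] < config.alpha)]
        required = list(sig.index)
        if not required:
            logger.warning("no cell type passed the survival screen; "
                           "filtering against the full vocabulary")
            required = sorted(annotation.vocabulary)
        kept, report = filter_by_celltype_expression(state["de_genes"],
                                                     annotation, required)
        selected = stepwise_select(design[kept], y) if kept else []
        state["stepwise"] = selected
        out = outdir / "stepwise_selected.tsv"
        ipio.write_table(pd.DataFrame({"gene": selected}), out,
                         meta={**meta, "n_candidates": len(kept),
                               "required_celltypes": ";".join(required),
                               "n_dropped_unannotated":
                                   len(report["unannotated"])}, index=False)
        return [out]

    run_stage("stepwise", stage_stepwise)

    # ---- stage 8: combination benchmarking --------------------------------
    def stage_benchmark():
        pools = {
            "candidate": state["stepwise"],
            "positive_control": [g for g in pc_set.gene_symbols
                                 if g in design.columns],
            "negative_control": [g for g in nc_set.gene_symbols
                                 if g in design.columns],
        }
        smallest = min((len(p) for p in pools.values() if len(p) > 0),
                       default=0)
        k = min(config.combo_k, smallest)
        if 0 < smallest < 2 * config.combo_k:
            # keep the draws diverse when a pool is small: sample about
            # half the pool, echoing the 20-of-87 proportion
            k = max(2, min(config.combo_k, smallest // 2))
        benches = {}
        outputs = []
        for i, (name, pool) in enumerate(pools.items()):
            if len(pool) < max(k, 1):
                logger.warning("pool %s too small (%d genes); skipped",
                               name, len(pool))
                continue
            bench = benchmark_random_combinations(
                pool, k=k, n_draws=config.n_draws, X=design, y=y,
                seed=config.seed + i, pool_name=name)
            benches[name] = bench
            out = outdir / f"benchmark_{name}.tsv"
            ipio.write_table(pd.DataFrame({"auc": bench.auc_values}), out,
                             meta={**meta, "pool": name, "k": k,
                                   "n_draws": config.n_draws,
                                   "pool_size": len(pool),
                                   "seed_used": config.seed + i,
                                   "evaluation": "in-sample"}, index=False)
            outputs.append(out)
        state["benches"] = benches
        state["combo_k"] = k
        return outputs

    run_stage("benchmark", stage_benchmark)

    # ---- stage 9: frequency profiling -------------------------------------
    def stage_frequency():
        benches = state["benches"]
        if "candidate" not in benches:
            raise ValueError("candidate pool missing from benchmark stage")
        if config.threshold_mode == "pc_mean" and "positive_control" in benches:
            threshold = float(benches["positive_control"].auc_values.mean())
        else:
            threshold = float(config.threshold_mode)
        profile = frequency_profile(benches["candidate"], threshold,
                                    top_m=config.top_m)
        state["profile"] = profile
        out = outdir / "frequency_profile.tsv"
        tbl = pd.DataFrame({"count": profile.counts,
                            "mean_auc": profile.mean_auc})
        tbl["in_top"] = tbl.index.isin(profile.top)
        ipio.write_table(tbl, out,
                         meta={**meta, "threshold": threshold,
                               "n_qualifying": profile.n_qualifying,
                               "top_m": config.top_m})
        return [out]

    run_stage("frequency", stage_frequency)

    # ---- stage 10: exhaustive panel search + leave-one-out ----------------
    def stage_panel():
        top = state["profile"].top
        result = exhaustive_panel_search(top, design, y)
        out = outdir / "panel.json"
        ipio.write_json({
            "panel": result.best_subset,
            "auc_in_sample": result.best_auc,
            "n_subsets_evaluated": result.n_subsets_evaluated,
            "intercept": result.model.intercept,
            "coefficients": dict(zip(result.model.gene_names,
                                     result.model.coefficients)),
            "leave_one_out": result.leave_one_out,
        }, out, meta={**meta, "evaluation": "in-sample"})
        return [out]

    run_stage("panel", stage_panel)

    ipio.write_json(manifest, manifest_path)
    return manifest
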