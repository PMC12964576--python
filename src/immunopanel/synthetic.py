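"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of a bulk renal-tumor cohort profiled
for immune infiltration and matched tumor/normal expression:

* each patient belongs to one of a small number of latent immune clusters;
  their 22-dimensional immune-cell fraction profile is a Dirichlet draw
  around the cluster's mean profile;
* expression is log-normal around a per-gene baseline; tumor means equal
  normal means times a planted fold change (>= 1, upregulated in tumor),
  so the planted FC is recovered exactly as noise goes to zero;
* survival times are exponential with per-patient hazard
  baseline * cluster multiplier * exp(sum of signal effects times the
  patient's standardized log tumor expression), with independent
  exponential censoring tuned to a target censoring rate plus an
  administrative follow-up horizon;
* the ground truth (cluster labels, DE genes, signal genes, latent death
  probabilities) is returned alongside the data so every downstream stage
  has a recovery target.

The generator does not attempt to emulate deconvolution error structure:
fractions are drawn directly from the latent clusters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LM22_CELL_TYPES",
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "plant_separable_clusters",
    "default_config",
    "generate_cohort",
    "make_celltype_annotation",
    "default_pools",
]

#: the 22 leukocyte subsets quantified by standard bulk deconvolution
LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of one simulated cohort.

    ``de_spec`` maps gene -> tumor/normal fold change (>= 1); ``signal_spec``
    maps gene -> effect on the log hazard per SD of log tumor expression.
    ``cluster_marker_genes`` maps cluster index -> genes whose tumor mean is
    multiplied by exp(cluster_marker_shift) in that cluster, giving the
    expression view a recoverable cluster structure.
    """

    n_patients: int = 300
    n_celltypes: int = 22
    n_clusters: int = 5
    cluster_weights: tuple[float, ...] | None = None
    cluster_profiles: tuple[tuple[float, ...], ...] | None = None
    fraction_concentration: float = 60.0
    n_genes: int = 2000
    immune_reg_fraction: float = 0.25
    de_spec: tuple[tuple[str, float], ...] = ()
    signal_spec: tuple[tuple[str, float], ...] = ()
    cluster_hazard: tuple[float, ...] | None = None
    baseline_hazard: float = 1e-4
    follow_up_days: float = 3650.0
    censor_rate: float = 0.3
    noise_sd: float = 0.6
    cluster_marker_genes: tuple[tuple[int, tuple[str, ...]], ...] = ()
    cluster_marker_shift: float = 1.0
    seed: int = 0

    # -- derived vocabulary -------------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    @property
    def n_immune_reg(self) -> int:
        return int(round(self.immune_reg_fraction * self.n_genes))

    @property
    def immune_reg_genes(self) -> list[str]:
        return self.gene_names[: self.n_immune_reg]

    @property
    def celltype_names(self) -> list[str]:
        if self.n_celltypes == len(LM22_CELL_TYPES):
            return list(LM22_CELL_TYPES)
        return [f"CT{i:02d}" for i in range(self.n_celltypes)]

    def resolved_weights(self) -> np.ndarray:
        if self.cluster_weights is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_weights, dtype=float)

    def resolved_hazard(self) -> np.ndarray:
        if self.cluster_hazard is None:
            return np.ones(self.n_clusters)
        return np.asarray(self.cluster_hazard, dtype=float)

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ConfigurationError("n_patients must be >= 10")
        if self.n_celltypes < 2 or self.n_clusters < 1 or self.n_genes < 1:
            raise ConfigurationError("sizes must be positive")
        w = self.resolved_weights()
        if w.size != self.n_clusters or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ConfigurationError("cluster_weights must be a probability vector")
        if self.cluster_profiles is not None:
            prof = np.asarray(self.cluster_profiles, dtype=float)
            if prof.shape != (self.n_clusters, self.n_celltypes):
                raise ConfigurationError("cluster_profiles shape mismatch")
            if np.any(prof < 0) or np.any(np.abs(prof.sum(axis=1) - 1.0) > 1e-8):
                raise ConfigurationError(
                    "each cluster_profile must be non-negative and sum to 1")
        h = self.resolved_hazard()
        if h.size != self.n_clusters or np.any(h <= 0):
            raise ConfigurationError("cluster_hazard must be positive per cluster")
        if self.baseline_hazard <= 0 or self.fraction_concentration <= 0:
            raise ConfigurationError("hazard and concentration must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0.0 <= self.immune_reg_fraction <= 1.0:
            raise ConfigurationError("immune_reg_fraction must be in [0, 1]")
        universe = set(self.gene_names)
        for gene, fc in self.de_spec:
            if gene not in universe:
                raise ConfigurationError(f"de_spec gene {gene!r} not in universe")
            if fc < 1.0:
                raise ConfigurationError(
                    f"planted fold change for {gene} must be >= 1 (got {fc})")
        for gene, _ in self.signal_spec:
            if gene not in universe:
                raise ConfigurationError(f"signal_spec gene {gene!r} not in universe")
        for cluster, genes in self.cluster_marker_genes:
            if not 0 <= cluster < self.n_clusters:
                raise ConfigurationError("marker cluster index out of range")
            if not set(genes) <= universe:
                raise ConfigurationError("marker genes not in universe")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic cohort, keyed by tumor sample ID."""

    cluster_label: pd.Series
    de_genes: dict[str, float]
    signal_genes: dict[str, float]
    immune_reg_genes: list[str]
    marker_genes: dict[int, list[str]]
    death_prob: pd.Series
    hazard: pd.Series


@dataclass(frozen=True)
class SyntheticCohort:
    tumor: pd.DataFrame
    normal: pd.DataFrame
    fractions: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth
    config: SyntheticCohortConfig


def plant_separable_clusters(config: SyntheticCohortConfig,
                             separation: float = 0.5) -> SyntheticCohortConfig:
    """Return a config whose cluster profiles are pairwise L1-separated.

    Profile c places mass ``separation`` on its own dominant cell type and
    spreads the rest uniformly, so every pair of profiles is at L1 distance
    2 * separation. Requires n_clusters <= n_celltypes (each cluster needs
    its own dominant cell) and separation in (0, 1].
    """
    if separation <= 0:
        raise ConfigurationError("separation must be > 0")
    if separation > 1:
        raise ConfigurationError("separation > 1 incompatible with the simplex")
    k, d = config.n_clusters, config.n_celltypes
    if k > d:
        raise ConfigurationError(
            f"cannot place {k} separated clusters in {d} cell types")
    base = (1.0 - separation) / d
    prof = np.full((k, d), base)
    prof[np.arange(k), np.arange(k)] += separation
    prof /= prof.sum(axis=1, keepdims=True)
    return dataclasses.replace(
        config, cluster_profiles=tuple(tuple(row) for row in prof))


def default_config(n_patients: int = 300, n_genes: int = 2000,
                   seed: int = 0, separation: float = 0.5,
                   **overrides) -> SyntheticCohortConfig:
    """The canonical study conditions used throughout the test-bed.

    Five immune clusters of equal weight, the last two at 2.5x hazard
    (poor-prognosis clusters). Within the immune-regulatory block
    (first 25% of genes):

    * genes 0-4 carry large tumor fold changes (50, 30, 25, 15, 10) and
      strong survival effects (0.5 per SD) -- high-index, prognostic genes;
    * genes 5-19 carry FC 4 and moderate effects (0.2);
    * genes 20-59 carry FC 4 only (upregulated but survival-neutral);
    * 25 marker genes per cluster (from index 100) give the expression
      view a cluster structure aligned with the immune view.

    A positive-control analogue of 63 genes with weak effects (0.1) sits
    just outside the immune-regulatory block; 365 genes from index 1000
    are reserved as the negative-control pool (no planted structure).
    """
    if n_genes < 1500:
        raise ConfigurationError("default_config expects n_genes >= 1500")
    names = [f"G{i:05d}" for i in range(n_genes)]
    n_ir = int(round(0.25 * n_genes))
    top_fc = [50.0, 30.0, 25.0, 15.0, 10.0]
    de = [(names[i], top_fc[i]) for i in range(5)]
    de += [(names[i], 4.0) for i in range(5, 60)]
    signal = [(names[i], 0.5) for i in range(5)]
    signal += [(names[i], 0.2) for i in range(5, 20)]
    signal += [(names[n_ir + i], 0.1) for i in range(63)]
    markers = tuple(
        (c, tuple(names[100 + 25 * c: 100 + 25 * (c + 1)])) for c in range(5))
    cfg = SyntheticCohortConfig(
        n_patients=n_patients,
        n_genes=n_genes,
        de_spec=tuple(de),
        signal_spec=tuple(signal),
        cluster_hazard=(1.0, 1.0, 1.0, 2.5, 2.5),
        cluster_marker_genes=markers,
        seed=seed,
        **overrides,
    )
    return plant_separable_clusters(cfg, separation=separation)


def _lognormal_noise(rng: np.random.Generator, sd: float,
                     shape: tuple[int, ...]) -> np.ndarray:
    """exp(sd*Z - sd^2/2): multiplicative noise with unit mean."""
    if sd == 0.0:
        return np.ones(shape)
    return np.exp(sd * rng.standard_normal(shape) - 0.5 * sd * sd)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one cohort; identical configs give bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes
    genes = config.gene_names
    patients = [f"P{i:04d}" for i in range(n)]
    tumor_ids = [p + "-T" for p in patients]
    normal_ids = [p + "-N" for p in patients]

    # latent immune clusters and fractions
    weights = config.resolved_weights()
    labels = rng.choice(config.n_clusters, size=n, p=weights)
    if config.cluster_profiles is None:
        profiles = plant_separable_clusters(config).cluster_profiles
    else:
        profiles = config.cluster_profiles
    prof = np.asarray(profiles, dtype=float)
    alpha = np.maximum(config.fraction_concentration * prof, 1e-3)
    fractions = np.empty((n, config.n_celltypes))
    for c in range(config.n_clusters):
        mask = labels == c
        if mask.any():
            fractions[mask] = rng.dirichlet(alpha[c], size=int(mask.sum()))

    # expression: log-normal around per-gene baselines
    baseline = rng.lognormal(mean=np.log(20.0), sigma=1.2, size=g)
    fc = np.ones(g)
    de_map = dict(config.de_spec)
    gene_pos = {name: i for i, name in enumerate(genes)}
    for gene, f in de_map.items():
        fc[gene_pos[gene]] = f
    normal_expr = baseline[:, None] * _lognormal_noise(rng, config.noise_sd, (g, n))
    tumor_mean = (baseline * fc)[:, None] * np.ones((g, n))
    for cluster, mgenes in config.cluster_marker_genes:
        idx = [gene_pos[m] for m in mgenes]
        cols = labels == cluster
        if cols.any():
            tumor_mean[np.ix_(idx, cols)] *= np.exp(config.cluster_marker_shift)
    tumor_expr = tumor_mean * _lognormal_noise(rng, config.noise_sd, (g, n))

    # survival: exponential with planted cluster and gene effects
    log_h = np.log(config.baseline_hazard) + np.log(
        config.resolved_hazard())[labels]
    for gene, beta in config.signal_spec:
        vals = np.log(tumor_expr[gene_pos[gene]] + 1e-9)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        log_h = log_h + beta * z
    hazard = np.exp(log_h)
    t_death = rng.exponential(1.0 / hazard)
    tau = config.follow_up_days
    if config.censor_rate > 0:
        c_rate = hazard.mean() * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        c_rate = 0.0
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(np.minimum(t_death, t_cens), tau)
    os_event = ((t_death <= t_cens) & (t_death <= tau)).astype(int)
    total = hazard + c_rate
    death_prob = hazard / total * (1.0 - np.exp(-total * tau))

    tumor = pd.DataFrame(tumor_expr, index=genes, columns=tumor_ids)
    normal = pd.DataFrame(normal_expr, index=genes, columns=normal_ids)
    fractions_df = pd.DataFrame(fractions, index=tumor_ids,
                                columns=config.celltype_names)
    clinical = pd.DataFrame({
        "sample_id": tumor_ids + normal_ids,
        "patient_id": patients + patients,
        "tissue": ["tumor"] * n + ["normal"] * n,
        "os_time_days": np.concatenate([os_time, os_time]),
        "os_event": np.concatenate([os_event, os_event]),
    }).set_index("sample_id")

    truth = GroundTruth(
        cluster_label=pd.Series(labels, index=tumor_ids, name="cluster"),
        de_genes=de_map,
        signal_genes=dict(config.signal_spec),
        immune_reg_genes=config.immune_reg_genes,
        marker_genes={c: list(mg) for c, mg in config.cluster_marker_genes},
        death_prob=pd.Series(death_prob, index=tumor_ids, name="death_prob"),
        hazard=pd.Series(hazard, index=tumor_ids, name="hazard"),
    )
    return SyntheticCohort(tumor=tumor, normal=normal, fractions=fractions_df,
                           clinical=clinical, truth=truth, config=config)


def make_celltype_annotation(config: SyntheticCohortConfig,
                             annotate_prob_immune: float = 0.9,
                             annotate_prob_other: float = 0.3,
                             ) -> dict[str, frozenset[str]]:
    """Gene -> cell-type annotation standing in for a reference expression atlas.

    Immune-regulatory genes are annotated to 1-3 cell types with high
    probability, biased toward the dominant cell types of the high-hazard
    clusters so planted candidates survive the cell-type filter; other
    genes are annotated sparsely. Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(101,)))
    cts = config.celltype_names
    hz = config.resolved_hazard()
    poor_clusters = np.argsort(hz)[-2:]
    # dominant cell type of cluster c is cell type c under the separable layout
    poor_cts = [cts[c] for c in poor_clusters if c < len(cts)]
    ir = set(config.immune_reg_genes)
    planted = {g for g, _ in config.de_spec} | {g for g, _ in config.signal_spec}
    annotation: dict[str, frozenset[str]] = {}
    for gene in config.gene_names:
        p = annotate_prob_immune if gene in ir else annotate_prob_other
        if gene in planted or rng.random() < p:
            n_extra = int(rng.integers(0, 3))
            chosen = set(rng.choice(len(cts), size=n_extra, replace=False))
            types = {cts[i] for i in chosen}
            if gene in planted and poor_cts:
                types.add(poor_cts[int(rng.integers(len(poor_cts)))])
            elif not types:
                types.add(cts[int(rng.integers(len(cts)))])
            annotation[gene] = frozenset(types)
    return annotation


def default_pools(config: SyntheticCohortConfig) -> dict[str, list[str]]:
    """Gene pools mirroring the benchmarking controls.

    ``positive_control``: the 63 weak-effect genes just outside the
    immune-regulatory block (literature-prognostic analogue).
    ``negative_control``: 365 genes with no planted structure (olfactory-
    receptor analogue). ``immune_regulation``: the flagged gene-set input.
    """
    names = config.gene_names
    n_ir = config.n_immune_reg
    if config.n_genes < 1365:
        raise ConfigurationError("pools require n_genes >= 1365")
    return {
        "immune_regulation": list(names[:n_ir]),
        "positive_control": list(names[n_ir: n_ir + 63]),
        "negative_control": list(names[1000:1365]),
    }
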