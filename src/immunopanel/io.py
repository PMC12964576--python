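"""Readers and writers for the pipeline's canonical file formats.

Tables travel as UTF-8 tab-separated values with Unix newlines; gene sets
as GMT; models, manifests and search results as JSON. Every writer embeds
the RNG seed and the parameters that produced the artifact as ``#``
comment lines (tables) or top-level fields (JSON), so outputs are
auditable in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gene_clustering import GeneSet
from .panel_selection import CelltypeAnnotation

logger = logging.getLogger("immunopanel")

__all__ = [
    "read_expression",
    "read_fractions",
    "read_clinical",
    "read_gmt",
    "write_gmt",
    "read_celltype_annotation",
    "write_celltype_annotation",
    "write_table",
    "read_table",
    "write_json",
]


class ParseError(ValueError):
    """Malformed input file."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no data columns (malformed header?)")
    return df


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        # +2: header line plus 1-based counting
        line = int(np.nonzero(df.index == gene)[0][0]) + 2
        raise ParseError(f"{path}: non-numeric value at gene {gene!r}, "
                         f"sample {sample!r} (line {line})")
    if out.isna().any().any():
        gene = out.isna().any(axis=1).idxmax()
        raise ParseError(f"{path}: missing value in row {gene!r}")
    return out


def read_expression(path) -> pd.DataFrame:
    """Genes-by-samples expression TSV (gene symbols in the first column).

    Symbols are uppercase-normalized; duplicate symbols are collapsed by
    mean with a warning; negative values are rejected naming the cell.
    """
    path = Path(path)
    df = _coerce_numeric(_read_tsv(path), path)
    df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        warnings.warn(f"{path.name}: duplicate gene symbols collapsed by "
                      f"mean: {dups[:5]}{'...' if len(dups) > 5 else ''}")
        logger.warning("%s: collapsed %d duplicate symbols", path, len(dups))
        df = df.groupby(level=0, sort=False).mean()
    neg = df.lt(0)
    if neg.any().any():
        gene = neg.any(axis=1).idxmax()
        sample = neg.loc[gene].idxmax()
        raise ParseError(f"{path}: negative expression at gene {gene!r}, "
                         f"sample {sample!r}")
    return df


def read_fractions(path, tol: float = 1e-6) -> pd.DataFrame:
    """Samples-by-cell-type immune fraction TSV; rows must sum to 1."""
    path = Path(path)
    df = _coerce_numeric(_read_tsv(path), path)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample IDs")
    if df.lt(0).any().any():
        raise ParseError(f"{path}: negative fractions")
    sums = df.sum(axis=1)
    off = (sums - 1.0).abs() > tol
    if off.any():
        raise ParseError(f"{path}: fraction rows not summing to 1: "
                         f"{list(df.index[off][:5])}")
    return df


_CLINICAL_COLS = ("patient_id", "tissue", "os_time_days", "os_event")


def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV indexed by sample_id.

    Requires columns patient_id, tissue, os_time_days, os_event.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    missing = [c for c in _CLINICAL_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample IDs")
    df["os_time_days"] = pd.to_numeric(df["os_time_days"], errors="raise")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")
    if not df["os_event"].isin((0, 1)).all():
        raise ParseError(f"{path}: os_event must be 0/1")
    if (df["os_time_days"] < 0).any():
        raise ParseError(f"{path}: negative survival times")
    return df


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: name, description, then tab-separated gene symbols."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has "
                                 f"{len(fields)} fields (need >= 3)")
            sets.append(GeneSet(name=fields[0], gene_symbols=tuple(fields[2:])))
    return sets


def write_gmt(sets, path, description: str = "immunopanel") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.gene_symbols]) + "\n")


def read_celltype_annotation(path) -> CelltypeAnnotation:
    """TSV with columns gene, celltypes (comma-separated list)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", "celltypes"} <= set(df.columns):
        raise ParseError(f"{path}: needs columns 'gene' and 'celltypes'")
    mapping = {}
    for _, row in df.iterrows():
        types = frozenset(t.strip() for t in str(row["celltypes"]).split(",")
                          if t.strip())
        if types:
            mapping[str(row["gene"]).upper()] = types
    return CelltypeAnnotation(mapping=mapping)


def write_celltype_annotation(annotation: Mapping[str, frozenset], path) -> None:
    rows = [{"gene": g, "celltypes": ",".join(sorted(v))}
            for g, v in sorted(annotation.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, meta: Mapping | None = None,
                index: bool = True) -> None:
    """TSV with '# key=value' provenance comment lines up top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write a synthetic cohort as the standard pipeline inputs.

    Emits expression TSVs (tumor, normal), fractions TSV, clinical TSV,
    ground-truth JSON, the immune-regulation / positive-control /
    negative-control GMTs, and the cell-type annotation TSV. Returns a
    name -> path mapping suitable for building a PipelineConfig.
    """
    from .gene_clustering import GeneSet
    from .synthetic import default_pools, make_celltype_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    meta = {"seed": cfg.seed, "n_patients": cfg.n_patients,
            "n_genes": cfg.n_genes}
    paths = {
        "expression_tumor": outdir / "expression_tumor.tsv",
        "expression_normal": outdir / "expression_normal.tsv",
        "fractions": outdir / "fractions.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
        "immune_gene_set": outdir / "immune_regulation.gmt",
        "pc_pool": outdir / "positive_control.gmt",
        "nc_pool": outdir / "negative_control.gmt",
        "annotation": outdir / "celltype_annotation.tsv",
    }
    write_table(cohort.tumor, paths["expression_tumor"], meta=meta)
    write_table(cohort.normal, paths["expression_normal"], meta=meta)
    write_table(cohort.fractions, paths["fractions"], meta=meta)
    cohort.clinical.reset_index().to_csv(paths["clinical"], sep="\t",
                                         index=False)
    truth = cohort.truth
    write_json({
        "cluster_label": truth.cluster_label,
        "de_genes": truth.de_genes,
        "signal_genes": truth.signal_genes,
        "immune_reg_genes": truth.immune_reg_genes,
        "marker_genes": {str(k): v for k, v in truth.marker_genes.items()},
        "death_prob": truth.death_prob,
    }, paths["truth"], meta=meta)
    pools = default_pools(cfg)
    write_gmt([GeneSet("IMMUNE_REGULATION", tuple(pools["immune_regulation"]))],
              paths["immune_gene_set"])
    write_gmt([GeneSet("POSITIVE_CONTROL", tuple(pools["positive_control"]))],
              paths["pc_pool"])
    write_gmt([GeneSet("NEGATIVE_CONTROL", tuple(pools["negative_control"]))],
              paths["nc_pool"])
    write_celltype_annotation(make_celltype_annotation(cfg),
                              paths["annotation"])
    return {k: str(v) for k, v in paths.items()}


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data: Mapping, path, meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(data)
    if meta:
        payload["_meta"] = dict(meta)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, default=_jsonify)
        fh.write("\n")
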