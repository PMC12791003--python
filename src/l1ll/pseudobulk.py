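"""Pseudo-bulk TE quantification from barcoded single-cell reads.

Single-cell (or single-nucleus) data cannot resolve individual TE loci per
cell, but pooling the reads of all cells assigned to a cluster produces a
bulk-like sample per cluster in which unique-mapping locus-level
quantification works. The steps are: per-sample cell QC (mitochondrial
content and detected-feature bounds), backtracking reads to clusters via
their barcode, per-cluster TE/gene counting, and normalization with
per-pseudocluster median-of-ratios size factors computed from gene counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import GeneModel, TELocus
from .quantify import (
    StrandedCountMatrix,
    count_genes,
    count_over_features,
    normalize_by_size_factors,
    size_factors_median_of_ratios,
)

logger = logging.getLogger(__name__)

METRICS_COLUMNS = ["barcode", "sample_id", "n_features", "percent_mito"]
ASSIGNMENT_COLUMNS = ["barcode", "sample_id", "cluster_id"]


def read_cell_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample_id": str})
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metrics table missing columns {missing}")
    return df[METRICS_COLUMNS]


def read_cluster_assignment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample_id": str})
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: assignment table missing columns {missing}")
    if df.duplicated(subset=["barcode", "sample_id"]).any():
        raise ValueError(f"{path}: duplicate (barcode, sample) assignment")
    return df[ASSIGNMENT_COLUMNS]


def qc_filter_cells(
    metrics: pd.DataFrame,
    mito_max: float = 10.0,
    upper_sd: float = 2.0,
    lower_sd: float = 1.0,
) -> dict[str, set[str]]:
    """Kept barcodes per sample after single-pass QC.

    A cell is removed when its mitochondrial percentage exceeds
    ``mito_max`` (strictly) or its detected-feature count lies strictly
    above ``mean + upper_sd * SD`` or strictly below ``mean - lower_sd *
    SD`` of its sample; boundary values are kept. The mean and SD are
    computed once on the pre-filter population of each sample.
    """
    kept: dict[str, set[str]] = {}
    for sample, grp in metrics.groupby("sample_id"):
        if len(grp) < 2:
            raise ValueError(f"sample {sample!r} has fewer than 2 cells; SD undefined")
        mean = grp["n_features"].mean()
        sd = grp["n_features"].std(ddof=1)
        ok = (
            (grp["percent_mito"] <= mito_max)
            & (grp["n_features"] <= mean + upper_sd * sd)
            & (grp["n_features"] >= mean - lower_sd * sd)
        )
        kept[str(sample)] = set(grp.loc[ok, "barcode"])
    return kept


def backtrack_reads(
    reads: pd.DataFrame,
    assignment: pd.DataFrame,
    kept: Mapping[str, set[str]] | None = None,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Partition barcoded reads by cluster.

    Reads without a barcode, with a barcode absent from the assignment, or
    whose cell failed QC (when ``kept`` is given) are discarded; the
    discarded count is returned alongside the per-cluster read tables.
    """
    if assignment.duplicated(subset=["barcode", "sample_id"]).any():
        raise ValueError("duplicate (barcode, sample) in assignment")
    amap = assignment.set_index(["sample_id", "barcode"])["cluster_id"]
    keys = pd.MultiIndex.from_arrays([reads["sample_id"], reads["barcode"]])
    clusters = pd.Series(
        amap.reindex(keys).to_numpy(), index=reads.index, name="cluster"
    )
    valid = reads["barcode"].notna() & clusters.notna()
    if kept is not None:
        in_kept = pd.Series(
            [
                (b in kept.get(s, set()))
                for s, b in zip(reads["sample_id"], reads["barcode"])
            ],
            index=reads.index,
        )
        valid &= in_kept
    n_discarded = int((~valid).sum())
    if n_discarded:
        logger.info("backtrack_reads: discarded %d reads without a kept, assigned barcode", n_discarded)
    groups = {
        str(cluster): grp.drop(columns="cluster")
        for cluster, grp in reads.assign(cluster=clusters)[valid].groupby("cluster")
    }
    return groups, n_discarded


@dataclass
class PseudobulkResult:
    te_counts: StrandedCountMatrix  # features x clusters
    gene_counts: pd.DataFrame  # genes x clusters (sense)
    size_factors: pd.Series
    normalized_te_sense: pd.DataFrame
    normalized_te_antisense: pd.DataFrame


def pseudobulk_quantify(
    groups: Mapping[str, pd.DataFrame],
    te_loci: Sequence[TELocus],
    genes: Sequence[GeneModel],
) -> PseudobulkResult:
    """Quantify TEs and genes per pseudocluster and normalize TE counts.

    Each cluster's pooled reads are counted like a bulk sample
    (unique-only); size factors are the median-of-ratios statistic over
    the per-cluster gene count matrix, and pseudobulked TE counts are
    divided by their cluster's factor.
    """
    if not groups:
        raise ValueError("no clusters to quantify")
    cluster_ids = sorted(groups)
    relabeled = []
    for cluster in cluster_ids:
        sub = groups[cluster].copy()
        sub["sample_id"] = cluster
        relabeled.append(sub)
    pooled = pd.concat(relabeled, ignore_index=True)
    te = count_over_features(pooled, te_loci, require_unique=True, samples=cluster_ids)
    gene_m = count_genes(pooled, genes, require_unique=True, samples=cluster_ids)
    zero = gene_m.sense.sum(axis=0) == 0
    if zero.any():
        bad = list(gene_m.sense.columns[zero])
        raise ValueError(f"cluster(s) {bad} have zero gene counts; size factor undefined")
    if len(cluster_ids) == 1:
        sf = pd.Series([1.0], index=cluster_ids, name="size_factor")
    else:
        sf = size_factors_median_of_ratios(gene_m.sense)
    norm_sense = normalize_by_size_factors(te.sense, sf).values
    norm_anti = normalize_by_size_factors(te.antisense, sf).values
    return PseudobulkResult(te, gene_m.sense, sf, norm_sense, norm_anti)


def cell_accounting(assignments: Mapping[str, pd.DataFrame]) -> dict[str, int]:
    """Nuclei counts per condition plus their total.

    ``assignments`` maps a condition name to its cell table (one row per
    nucleus). Returns per-condition counts and a ``total`` entry.
    """
    out = {cond: int(len(df)) for cond, df in assignments.items()}
    out["total"] = sum(out.values())
    return out
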