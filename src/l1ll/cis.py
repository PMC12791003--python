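"""Cis-regulation of genes by L1 promoters.

Consumes differential-expression tables (gene, log2 fold change, adjusted
p) from an upstream DE tool and asks whether transcriptional silencing of
L1s affects nearby genes: genes are classified up/down/ns, downregulated
genes are binned by distance to the nearest full-length L1, a cross-guide
consistency rule intersects several comparisons, and exon-level counts of
a host gene are split around an intronic L1 to detect transcripts driven
by the L1 antisense promoter (downstream exons high and silenced by
CRISPRi, upstream canonical exons low and unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    GeneModel,
    NearestFeature,
    TELocus,
    nearest_feature_distance,
)
from .intervals import GenomicInterval

DE_COLUMNS = ["gene_id", "log2fc", "padj"]


def read_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Read a DE result table (TSV) into the canonical three-column layout."""
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = df[[gene_col, lfc_col, padj_col]].copy()
    out.columns = DE_COLUMNS
    return out


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[DE_COLUMNS].copy()
    out.columns = ["gene_id", "log2FoldChange", "padj"]
    out.to_csv(path, sep="\t", index=False)


@dataclass
class DEClassification:
    down: set[str]
    up: set[str]
    ns: set[str]


def classify_de(
    records: pd.DataFrame,
    padj_thr: float = 0.05,
    lfc_thr: float = 1.0,
    include_boundary: bool = True,
) -> DEClassification:
    """Partition genes of one comparison into down / up / not-significant.

    Down: ``padj < padj_thr`` and ``log2fc <= -lfc_thr``; up mirrored.
    Undefined padj is not significant. The fold-change boundary is
    inclusive by default (magnitude reading of the threshold).
    """
    if records["gene_id"].duplicated().any():
        dup = records.loc[records["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene {dup!r} in comparison")
    padj = records["padj"]
    lfc = records["log2fc"]
    sig = padj.notna() & (padj < padj_thr)
    if include_boundary:
        down_mask = sig & (lfc <= -lfc_thr)
        up_mask = sig & (lfc >= lfc_thr)
    else:
        down_mask = sig & (lfc < -lfc_thr)
        up_mask = sig & (lfc > lfc_thr)
    genes = records["gene_id"]
    down = set(genes[down_mask])
    up = set(genes[up_mask])
    ns = set(genes) - down - up
    return DEClassification(down, up, ns)


def cis_assignment(
    down_genes: set[str],
    genes: Sequence[GeneModel],
    loci: Sequence[TELocus],
    cutoff: int = 50_000,
) -> pd.DataFrame:
    """Bin downregulated genes by distance to the nearest (silenced) L1.

    ``loci`` should be prefiltered to the relevant set (full-length young,
    optionally restricted to CRISPRi-silenced loci). Returns one row per
    gene with columns ``gene_id, bin, nearest_locus, distance``.
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for gene_id in sorted(down_genes):
        if gene_id not in by_id:
            raise KeyError(f"gene {gene_id!r} absent from the gene annotation")
        nf: NearestFeature = nearest_feature_distance(by_id[gene_id], loci, cutoff)
        rows.append((gene_id, nf.bin, nf.locus_id, nf.distance))
    return pd.DataFrame(rows, columns=["gene_id", "bin", "nearest_locus", "distance"])


def bin_counts(assignment: pd.DataFrame) -> pd.Series:
    """Gene counts per distance bin from a :func:`cis_assignment` table."""
    return assignment["bin"].value_counts()


def consistent_de(
    base: pd.DataFrame,
    others: Sequence[pd.DataFrame],
    base_thr: float = 0.25,
) -> tuple[set[str], set[str]]:
    """Genes changing consistently across all comparisons.

    A gene is consistently upregulated when its base-comparison log2FC
    exceeds ``base_thr`` and its log2FC is positive in every other
    comparison; consistently downregulated is mirrored. Genes with an
    undefined fold change in any required comparison are excluded.
    Returns ``(consistent_up, consistent_down)``.
    """
    base_lfc = base.set_index("gene_id")["log2fc"]
    other_lfcs = [o.set_index("gene_id")["log2fc"] for o in others]
    up, down = set(), set()
    for gene, lfc in base_lfc.items():
        if pd.isna(lfc):
            continue
        vals = [o.get(gene, np.nan) for o in other_lfcs]
        if any(pd.isna(v) for v in vals):
            continue
        if lfc > base_thr and all(v > 0 for v in vals):
            up.add(gene)
        elif lfc < -base_thr and all(v < 0 for v in vals):
            down.add(gene)
    return up, down


def coding_noncoding_split(
    genes: set[str], biotypes: Mapping[str, str]
) -> dict[str, int]:
    """Tally a gene set by biotype; unknown biotypes count as ``other``."""
    counts = {"protein_coding": 0, "lncRNA": 0, "other": 0}
    for gene in genes:
        biotype = biotypes.get(gene, "other")
        if biotype not in counts:
            biotype = "other"
        counts[biotype] += 1
    return counts


# ---------------------------------------------------------------------------
# exon usage around an intronic L1


@dataclass
class ExonCounts:
    """Normalized per-exon counts of one gene, with an intronic L1 position.

    ``exons`` are in transcript order (5' to 3' of the gene); ``counts``
    maps condition name to an array of normalized counts, one per exon.
    """

    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    counts: dict[str, np.ndarray]
    l1_position: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for cond, values in self.counts.items():
            if len(values) != len(self.exons):
                raise ValueError(
                    f"{self.gene_id}: condition {cond!r} has {len(values)} values for "
                    f"{len(self.exons)} exons"
                )


@dataclass
class ExonUsageSplit:
    upstream_mean: dict[str, float]
    downstream_mean: dict[str, float]
    per_exon: pd.DataFrame
    l1_promoter_pattern: bool


def exon_usage_split(
    ec: ExonCounts,
    control: str = "control",
    treatment: str = "treatment",
    upstream_fold_tol: float = 1.5,
) -> ExonUsageSplit:
    """Split exon expression upstream/downstream of an intronic L1.

    Exons are partitioned in transcript orientation around the planted L1
    position; an exon overlapping the position is treated as downstream
    (the element transcribes into it). The L1-promoter pattern flag is
    true when downstream exons dominate the control condition, drop under
    treatment, and upstream exon means stay within ``upstream_fold_tol``
    of each other — the signature of an L1-driven alternative isoform.
    """
    span_start = min(ex.start for ex in ec.exons)
    span_end = max(ex.end for ex in ec.exons)
    if not (span_start <= ec.l1_position < span_end):
        raise ValueError(
            f"{ec.gene_id}: L1 position {ec.l1_position} outside gene span "
            f"[{span_start}, {span_end})"
        )
    if ec.strand == "+":
        upstream_mask = np.array([ex.end <= ec.l1_position for ex in ec.exons])
    else:
        upstream_mask = np.array([ex.start >= ec.l1_position for ex in ec.exons])
    if not upstream_mask.any() or upstream_mask.all():
        side = "upstream" if not upstream_mask.any() else "downstream"
        raise ValueError(f"{ec.gene_id}: no {side} exon relative to the L1 position")
    up_mean = {c: float(np.mean(v[upstream_mask])) for c, v in ec.counts.items()}
    down_mean = {c: float(np.mean(v[~upstream_mask])) for c, v in ec.counts.items()}
    for cond in (control, treatment):
        if cond not in ec.counts:
            raise KeyError(f"{ec.gene_id}: condition {cond!r} absent")
    lo, hi = sorted((up_mean[control], up_mean[treatment]))
    upstream_stable = (hi == 0) if lo == 0 else (hi / lo < upstream_fold_tol)
    flag = (
        down_mean[control] > up_mean[control]
        and down_mean[treatment] < down_mean[control]
        and upstream_stable
    )
    per_exon = pd.DataFrame(
        {
            "exon_index": np.arange(len(ec.exons)),
            "start": [ex.start for ex in ec.exons],
            "end": [ex.end for ex in ec.exons],
            "side": np.where(upstream_mask, "upstream", "downstream"),
            **{f"mean_{c}": v for c, v in ec.counts.items()},
        }
    )
    return ExonUsageSplit(up_mean, down_mean, per_exon, bool(flag))
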