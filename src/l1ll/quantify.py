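"""Stranded locus-level read counting and normalization.

Reads (aligned fragments) are held in a pandas DataFrame with the columns
of :data:`READ_COLUMNS`. Counting assigns each uniquely mapped fragment to
at most one feature — the one it overlaps most, ties resolved towards the
leftmost feature start — and splits TE counts into a sense and an
antisense block depending on whether the fragment's transcription strand
matches the element strand. Gene counting is sense-only over the exon
union, mirroring a reversely-stranded featureCounts run.

Normalization follows the bulk RNA-seq convention: size factors are the
median-of-ratios statistic computed from *gene* counts, and TE counts are
divided by those per-sample factors. A locus is called "expressed" in a
condition when at least one of the condition's samples has a normalized
count above the threshold (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import GeneModel, TELocus
from .intervals import GenomicInterval, merge_intervals

#: Canonical read-table columns. ``barcode`` may be empty/NaN for bulk data.
READ_COLUMNS = ["chrom", "start", "end", "strand", "sample_id", "unique", "barcode"]


def make_read_table(rows: Iterable[Mapping | tuple]) -> pd.DataFrame:
    """Build a read table from dicts or ``READ_COLUMNS``-ordered tuples."""
    rows = list(rows)
    if not rows:
        return pd.DataFrame(columns=READ_COLUMNS)
    df = pd.DataFrame(rows)
    if df.shape[1] == len(READ_COLUMNS) and not set(READ_COLUMNS) <= set(df.columns):
        df.columns = READ_COLUMNS
    if "barcode" not in df.columns:
        df["barcode"] = pd.NA
    return df[READ_COLUMNS]


def read_read_table(path: str | Path) -> pd.DataFrame:
    """Read the documented TSV read-table dialect."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "strand": str, "sample_id": str, "barcode": str},
    )
    missing = [c for c in READ_COLUMNS if c not in df.columns and c != "barcode"]
    if missing:
        raise ValueError(f"{path}: read table missing columns {missing}")
    if "barcode" not in df.columns:
        df["barcode"] = pd.NA
    df["unique"] = df["unique"].astype(bool)
    return df[READ_COLUMNS]


def write_read_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sam(
    path: str | Path,
    sample_id: str,
    unique_mapq: int = 255,
    mate_flip: bool = True,
    barcode_tag: str = "CB",
) -> pd.DataFrame:
    """Read fragments from a SAM/BAM file into the read-table layout.

    One row per fragment: for proper pairs only the first mate is visited
    and the template span is used. ``mate_flip`` applies the dUTP-protocol
    correction (the first mate's orientation is opposite the transcript,
    i.e. featureCounts ``-s 2`` semantics). Uniqueness is the ``NH`` tag
    when present, else ``MAPQ >= unique_mapq``.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired:
                if not aln.is_read1:
                    continue
                if aln.is_proper_pair and aln.template_length != 0:
                    start = min(aln.reference_start, aln.next_reference_start)
                    end = start + abs(aln.template_length)
                else:
                    start, end = aln.reference_start, aln.reference_end
            else:
                start, end = aln.reference_start, aln.reference_end
            strand = "-" if aln.is_reverse else "+"
            if mate_flip:
                strand = "-" if strand == "+" else "+"
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality >= unique_mapq
            barcode = aln.get_tag(barcode_tag) if aln.has_tag(barcode_tag) else None
            rows.append(
                (aln.reference_name, start, end, strand, sample_id, unique, barcode)
            )
    return make_read_table(rows)


# ---------------------------------------------------------------------------
# feature index and read assignment


@dataclass
class _Feature:
    fid: str
    strand: str
    intervals: tuple[GenomicInterval, ...]
    anchor_start: int  # leftmost start, used for tie-breaking


class FeatureIndex:
    """Assigns reads to features by largest overlap.

    Uses a vectorised binary-search path when the per-chromosome interval
    set is disjoint (the common case for curated TE annotations), and an
    interval-tree path otherwise. Both paths apply the same rule: the
    feature with the largest total overlap wins; ties go to the feature
    with the smaller anchor start, then the lexicographically smaller id.
    """

    def __init__(self, features: Sequence[_Feature]):
        self.features = list(features)
        self.strands = np.array([f.strand for f in self.features])
        order = sorted(
            range(len(self.features)),
            key=lambda i: (self.features[i].anchor_start, self.features[i].fid),
        )
        self.tie_rank = np.empty(len(self.features), dtype=np.int64)
        self.tie_rank[order] = np.arange(len(self.features))

        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for fi, feat in enumerate(self.features):
            for iv in feat.intervals:
                per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fi))
        self._index: dict[str, tuple] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            fidx = np.array([f for _, _, f in ivs], dtype=np.int64)
            disjoint = bool(np.all(starts[1:] >= ends[:-1]))
            tree = None
            if not disjoint:
                tree = IntervalTree()
                for s, e, f in ivs:
                    tree.addi(s, e, f)
            self._index[chrom] = (starts, ends, fidx, disjoint, tree)

    def _resolve(
        self, r_start: int, r_end: int, candidates: Iterable[tuple[int, int, int]],
        allowed_strand: str | None,
    ) -> int:
        """Pick one feature among candidate intervals ``(start, end, fidx)``."""
        totals: dict[int, int] = {}
        for s, e, fi in candidates:
            if allowed_strand is not None and self.strands[fi] != allowed_strand:
                continue
            ov = min(r_end, e) - max(r_start, s)
            if ov > 0:
                totals[fi] = totals.get(fi, 0) + ov
        if not totals:
            return -1
        return min(totals, key=lambda fi: (-totals[fi], self.tie_rank[fi]))

    def assign(
        self, reads: pd.DataFrame, require_same_strand: bool = False
    ) -> np.ndarray:
        """Feature index per read (-1 = unassigned)."""
        n = len(reads)
        out = np.full(n, -1, dtype=np.int64)
        chroms = reads["chrom"].to_numpy()
        starts = reads["start"].to_numpy(dtype=np.int64)
        ends = reads["end"].to_numpy(dtype=np.int64)
        strands = reads["strand"].to_numpy()
        for chrom in pd.unique(chroms):
            entry = self._index.get(chrom)
            if entry is None:
                continue
            f_starts, f_ends, fidx, disjoint, tree = entry
            ridx = np.flatnonzero(chroms == chrom)
            rs, re_ = starts[ridx], ends[ridx]
            if disjoint:
                lo = np.searchsorted(f_ends, rs, side="right")
                hi = np.searchsorted(f_starts, re_, side="left")
                ncand = hi - lo
                single = ncand == 1
                if single.any():
                    feat = fidx[lo[single]]
                    tgt = ridx[single]
                    if require_same_strand:
                        ok = self.strands[feat] == strands[tgt]
                        out[tgt[ok]] = feat[ok]
                    else:
                        out[tgt] = feat
                for k in np.flatnonzero(ncand > 1):
                    i = ridx[k]
                    cands = [
                        (f_starts[j], f_ends[j], fidx[j]) for j in range(lo[k], hi[k])
                    ]
                    out[i] = self._resolve(
                        rs[k], re_[k], cands,
                        strands[i] if require_same_strand else None,
                    )
            else:
                for k, i in enumerate(ridx):
                    hits = tree.overlap(rs[k], re_[k])
                    cands = [(h.begin, h.end, h.data) for h in hits]
                    out[i] = self._resolve(
                        rs[k], re_[k], cands,
                        strands[i] if require_same_strand else None,
                    )
        return out


def _locus_features(loci: Sequence[TELocus]) -> list[_Feature]:
    return [
        _Feature(l.locus_id, l.interval.strand, (l.interval,), l.interval.start)
        for l in loci
    ]


def _gene_features(genes: Sequence[GeneModel], mode: str) -> list[_Feature]:
    feats = []
    for g in genes:
        if mode == "exon_union":
            merged = tuple(
                GenomicInterval(iv.chrom, iv.start, iv.end, g.strand)
                for iv in merge_intervals(g.exons)
            )
            if not merged:
                merged = (g.interval,)
        elif mode == "gene_body":
            merged = (g.interval,)
        else:
            raise ValueError(f"unknown gene counting mode {mode!r}")
        feats.append(_Feature(g.gene_id, g.strand, merged, g.interval.start))
    return feats


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class StrandedCountMatrix:
    """Features x samples integer counts, with an optional antisense block."""

    sense: pd.DataFrame
    antisense: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.antisense is not None:
            if not self.sense.index.equals(self.antisense.index) or not self.sense.columns.equals(
                self.antisense.columns
            ):
                raise ValueError("sense and antisense blocks must share dimensions")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.sense.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sense.columns)

    def total_count(self) -> int:
        total = int(self.sense.to_numpy().sum())
        if self.antisense is not None:
            total += int(self.antisense.to_numpy().sum())
        return total


def _count(
    reads: pd.DataFrame,
    index: FeatureIndex,
    feature_ids: list[str],
    samples: Sequence[str] | None,
    require_unique: bool,
    require_same_strand: bool,
    stranded_blocks: bool,
) -> StrandedCountMatrix:
    if samples is None:
        samples = list(pd.unique(reads["sample_id"]))
    if require_unique:
        reads = reads[reads["unique"].astype(bool)]
    assigned = index.assign(reads, require_same_strand=require_same_strand)
    hit = assigned >= 0
    feat_pos = assigned[hit]
    sample_codes = pd.Categorical(reads["sample_id"], categories=samples).codes
    samp_pos = sample_codes[hit]
    keep = samp_pos >= 0
    feat_pos, samp_pos = feat_pos[keep], samp_pos[keep]
    shape = (len(feature_ids), len(samples))
    if stranded_blocks:
        read_strands = reads["strand"].to_numpy()[hit][keep]
        is_sense = read_strands == index.strands[feat_pos]
        sense = np.zeros(shape, dtype=np.int64)
        anti = np.zeros(shape, dtype=np.int64)
        np.add.at(sense, (feat_pos[is_sense], samp_pos[is_sense]), 1)
        np.add.at(anti, (feat_pos[~is_sense], samp_pos[~is_sense]), 1)
        return StrandedCountMatrix(
            pd.DataFrame(sense, index=feature_ids, columns=list(samples)),
            pd.DataFrame(anti, index=feature_ids, columns=list(samples)),
        )
    sense = np.zeros(shape, dtype=np.int64)
    np.add.at(sense, (feat_pos, samp_pos), 1)
    return StrandedCountMatrix(pd.DataFrame(sense, index=feature_ids, columns=list(samples)))


def count_over_features(
    reads: pd.DataFrame,
    loci: Sequence[TELocus],
    require_unique: bool = True,
    samples: Sequence[str] | None = None,
) -> StrandedCountMatrix:
    """Count fragments over TE loci, split into sense/antisense blocks.

    Each (unique) fragment increments exactly one locus: the one it
    overlaps most. The sense block is incremented when the fragment's
    transcription strand equals the element strand, else the antisense
    block. Fragments overlapping no locus are skipped.
    """
    index = FeatureIndex(_locus_features(loci))
    return _count(
        reads, index, [l.locus_id for l in loci], samples,
        require_unique, require_same_strand=False, stranded_blocks=True,
    )


def count_genes(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    mode: str = "exon_union",
    require_same_strand: bool = True,
    require_unique: bool = True,
    samples: Sequence[str] | None = None,
) -> StrandedCountMatrix:
    """Count fragments over genes (sense-only block).

    A fragment is counted for a gene iff it overlaps the gene's exon union
    (``mode='exon_union'``; ``'gene_body'`` uses the full gene span) and,
    when ``require_same_strand``, matches the gene strand. Overlap with
    several genes is resolved by largest exon-union overlap.
    """
    index = FeatureIndex(_gene_features(genes, mode))
    return _count(
        reads, index, [g.gene_id for g in genes], samples,
        require_unique, require_same_strand=require_same_strand, stranded_blocks=False,
    )


# ---------------------------------------------------------------------------
# normalization


def size_factors_median_of_ratios(gene_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a genes x samples count matrix.

    For each gene with strictly positive counts in every sample, the ratio
    of its count to its geometric mean across samples is formed; the size
    factor of a sample is the median of these ratios. No rescaling is
    applied afterwards.
    """
    counts = gene_counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; a pseudo-reference "
            "fallback would be required and is disabled"
        )
    logc = np.log(counts[positive])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=gene_counts.columns, name="size_factor")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    normalization: str  # size_factor | rpkm | log2p1

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_by_size_factors(
    counts: pd.DataFrame, size_factors: pd.Series
) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in counts.columns if s not in size_factors.index]
    if missing:
        raise ValueError(f"no size factor for samples {missing}")
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = counts / size_factors.reindex(counts.columns)
    return NormalizedMatrix(values, "size_factor")


def rpkm(
    counts: pd.DataFrame,
    feature_lengths: pd.Series | Mapping[str, int],
    library_sizes: pd.Series | Mapping[str, int],
) -> NormalizedMatrix:
    """Reads per kilobase of feature per million mapped reads."""
    lengths = pd.Series(feature_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("feature lengths must be positive and defined for all features")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive and defined for all samples")
    values = counts.mul(1e9).div(lengths, axis=0).div(libs, axis=1)
    return NormalizedMatrix(values, "rpkm")


def log2_heatmap_transform(norm: NormalizedMatrix) -> NormalizedMatrix:
    """log2(x + 1) pseudo-count transform used for heatmap displays."""
    if (norm.values.to_numpy() < 0).any():
        raise ValueError("values must be non-negative")
    return NormalizedMatrix(np.log2(norm.values + 1.0), "log2p1")


# ---------------------------------------------------------------------------
# expressed-locus calling


def call_expressed(
    norm: NormalizedMatrix,
    samples: Sequence[str],
    threshold: float = 2.0,
) -> set[str]:
    """Features whose normalized count exceeds ``threshold`` (strictly) in
    at least one of the given condition samples."""
    if not samples:
        raise ValueError("samples must be a non-empty list")
    missing = [s for s in samples if s not in norm.values.columns]
    if missing:
        raise ValueError(f"samples {missing} absent from matrix")
    sub = norm.values[list(samples)]
    mask = (sub > threshold).any(axis=1)
    return set(sub.index[mask])


def partition_expression_across_conditions(
    expressed_in_a: set[str],
    norm_b: NormalizedMatrix,
    samples_b: Sequence[str],
    threshold: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Split loci expressed in condition A into silenced/detected in B.

    Returns ``(silenced_in_b, detected_in_b)``: a disjoint, exhaustive
    partition of ``expressed_in_a``. Detected loci are those also called
    expressed in condition B.
    """
    missing = expressed_in_a - set(norm_b.values.index)
    if missing:
        raise ValueError(f"features missing from condition-B matrix: {sorted(missing)[:5]}")
    expressed_b = call_expressed(norm_b, samples_b, threshold)
    detected = expressed_in_a & expressed_b
    silenced = expressed_in_a - detected
    return silenced, detected


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
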