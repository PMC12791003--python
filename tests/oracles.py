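"""Independent brute-force oracles used to validate the optimized paths.

Every function here is a direct O(n*m) transcription of the counting /
intersection rules, kept deliberately free of the package's index
structures so test comparisons are meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_intersect(a, b, min_overlap=1, match_strand=False):
    pairs = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            if match_strand and x.strand != y.strand:
                continue
            if min(x.end, y.end) - max(x.start, y.start) >= min_overlap:
                pairs.append((i, j))
    return pairs


def brute_nearest(gene, loci, cutoff=50_000):
    """(distance, locus_id, bin) by exhaustive pairwise comparison."""
    giv = gene.interval
    best = None
    for locus in loci:
        liv = locus.interval
        if liv.chrom != giv.chrom:
            continue
        overlap = min(giv.end, liv.end) - max(giv.start, liv.start)
        if overlap > 0:
            dist, ov = 0.0, True
        else:
            dist, ov = float(max(liv.start - giv.end, giv.start - liv.end, 0)), False
        key = (dist, not ov, liv.start, locus.locus_id)
        if best is None or key < best:
            best = key
    if best is None:
        return (float("inf"), None, "beyond_cutoff")
    dist, no_ov, _, locus_id = best
    if dist == 0 and not no_ov:
        return (0.0, locus_id, "intragenic")
    return (dist, locus_id, "within_cutoff" if dist <= cutoff else "beyond_cutoff")


def _assign_read(r_chrom, r_start, r_end, r_strand, features, require_same_strand):
    """features: list of (fid, strand, anchor_start, [(chrom, start, end), ...])."""
    totals = {}
    for fid, strand, anchor, segments in features:
        if require_same_strand and strand != r_strand:
            continue
        ov = sum(
            max(0, min(r_end, e) - max(r_start, s))
            for c, s, e in segments
            if c == r_chrom
        )
        if ov > 0:
            totals[fid] = (ov, anchor)
    if not totals:
        return None
    return min(totals, key=lambda f: (-totals[f][0], totals[f][1], f))


def brute_count_loci(reads: pd.DataFrame, loci, require_unique=True):
    """Per-locus sense/antisense counts by per-read assignment."""
    features = [
        (l.locus_id, l.interval.strand, l.interval.start,
         [(l.interval.chrom, l.interval.start, l.interval.end)])
        for l in loci
    ]
    samples = list(pd.unique(reads["sample_id"]))
    sense = pd.DataFrame(0, index=[l.locus_id for l in loci], columns=samples)
    anti = sense.copy()
    strand_of = {l.locus_id: l.interval.strand for l in loci}
    for row in reads.itertuples():
        if require_unique and not row.unique:
            continue
        fid = _assign_read(row.chrom, row.start, row.end, row.strand, features, False)
        if fid is None:
            continue
        if strand_of[fid] == row.strand:
            sense.loc[fid, row.sample_id] += 1
        else:
            anti.loc[fid, row.sample_id] += 1
    return sense, anti


def brute_count_genes(reads: pd.DataFrame, genes, require_same_strand=True,
                      require_unique=True):
    """Per-gene counts over the merged exon union."""
    features = []
    for g in genes:
        merged = []
        for ex in sorted(g.exons, key=lambda x: x.start):
            if merged and ex.start <= merged[-1][2]:
                merged[-1] = (ex.chrom, merged[-1][1], max(merged[-1][2], ex.end))
            else:
                merged.append((ex.chrom, ex.start, ex.end))
        features.append((g.gene_id, g.strand, g.interval.start, merged))
    samples = list(pd.unique(reads["sample_id"]))
    counts = pd.DataFrame(0, index=[g.gene_id for g in genes], columns=samples)
    for row in reads.itertuples():
        if require_unique and not row.unique:
            continue
        fid = _assign_read(
            row.chrom, row.start, row.end, row.strand, features, require_same_strand
        )
        if fid is not None:
            counts.loc[fid, row.sample_id] += 1
    return counts


def pooled_t(x, y):
    """Closed-form pooled-variance two-sample t and two-sided p."""
    from scipy import stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), nx + ny - 2)
    return t, p
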