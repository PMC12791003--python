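"""Transposable-element and gene annotations.

Models RepeatMasker-derived L1 copies (:class:`TELocus`) and gene models
with exon structure (:class:`GeneModel`), and derives the genomic windows
the downstream analyses intersect against: the 5' promoter window of a
full-length element, flank-expanded peaks, gene-to-locus distances and
genomic-context (intergenic / intragenic sense / antisense) labels.

Full-length, evolutionarily young L1s are the elements longer than 6 kb
belonging to the L1HS-L1PA4 subfamilies; only these retain an intact
internal bidirectional promoter in the 5'UTR, which is the first ~900 bp of
the element in element orientation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .intervals import GenomicInterval, overlap_length

#: Subfamilies with intact promoters: human-specific (L1HS) and
#: hominoid-specific (L1PA2-L1PA4) lineages.
YOUNG_SUBFAMILIES = frozenset({"L1HS", "L1PA2", "L1PA3", "L1PA4"})

#: Minimum element span for a full-length copy, exclusive (">6 kb").
FULL_LENGTH_BP = 6000

#: Default promoter span: the first 900 bp of the element 5' end.
PROMOTER_SPAN_BP = 900

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TELocus:
    """One annotated transposable-element copy."""

    locus_id: str
    interval: GenomicInterval
    subfamily: str
    family: str = "L1"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if not self.subfamily:
            raise ValueError(f"{self.locus_id}: subfamily must be non-empty")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A gene with an ordered exon chain on one strand."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: gene strand must be + or -")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(f"{self.gene_id}: exon on wrong chrom/strand")
            if ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class PromoterWindow:
    """The 5'-most ``span`` bp of a locus, in element orientation."""

    locus_id: str
    interval: GenomicInterval
    span: int

    def __post_init__(self) -> None:
        if self.span != self.interval.length:
            raise ValueError(f"{self.locus_id}: span must equal interval length")


class NearestFeature(NamedTuple):
    distance: float
    locus_id: str | None
    bin: str


BIN_INTRAGENIC = "intragenic"
BIN_WITHIN = "within_cutoff"
BIN_BEYOND = "beyond_cutoff"


# ---------------------------------------------------------------------------
# readers / writers


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


def read_te_annotation(
    path: str | Path,
    fmt: str | None = None,
    subfamily_key: str = "gene_id",
    locus_key: str = "transcript_id",
    family_key: str = "family_id",
) -> list[TELocus]:
    """Read TE loci from a GTF (TEtranscripts-style attributes) or BED6 file.

    GTF coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention. Locus ids are taken from ``locus_key`` (GTF) or
    from the BED name field; when a BED name does not carry an explicit id
    (``id|subfamily|family``) a stable id is generated from the name and
    coordinates.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    loci: list[TELocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    chrom, _, _, start, end, _, strand, _, attr_text = fields[:9]
                    attrs = _parse_gtf_attributes(attr_text)
                    subfamily = attrs.get(subfamily_key, "")
                    family = attrs.get(family_key, "L1")
                    interval = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                    locus_id = attrs.get(
                        locus_key,
                        f"{subfamily}_{chrom}_{interval.start}_{interval.end}",
                    )
                else:
                    if len(fields) < 4:
                        raise ValueError("expected >= 4 tab-separated BED fields")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                    parts = name.split("|")
                    if len(parts) == 3:
                        locus_id, subfamily, family = parts
                    else:
                        subfamily, family = name, "L1"
                        locus_id = f"{name}_{chrom}_{start}_{end}"
                    interval = GenomicInterval(chrom, start, end, strand)
                locus = TELocus(locus_id, interval, subfamily, family)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if locus.locus_id in seen:
                raise ValueError(f"{path}: duplicate locus_id {locus.locus_id!r} at line {lineno}")
            seen.add(locus.locus_id)
            loci.append(locus)
    return loci


def write_te_bed(loci: Iterable[TELocus], path: str | Path) -> None:
    """Write loci as BED6; the name field carries ``locus_id|subfamily|family``."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            name = f"{locus.locus_id}|{locus.subfamily}|{locus.family}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_te_gtf(loci: Iterable[TELocus], path: str | Path) -> None:
    """Write loci as a TEtranscripts-style GTF (gene_id = subfamily)."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            attrs = (
                f'gene_id "{locus.subfamily}"; transcript_id "{locus.locus_id}"; '
                f'family_id "{locus.family}"; class_id "LINE";'
            )
            fh.write(
                f"{iv.chrom}\trmsk\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_gene_annotation(
    path: str | Path,
    biotype_keys: Sequence[str] = ("gene_biotype", "gene_type"),
) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GTF file."""
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 9:
                    raise ValueError("expected 9 tab-separated GTF fields")
                chrom, _, feature, start, end, _, strand, _, attr_text = fields[:9]
                attrs = _parse_gtf_attributes(attr_text)
                gene_id = attrs["gene_id"]
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if gene_id not in meta:
                order.append(gene_id)
                biotype = next(
                    (attrs[k] for k in biotype_keys if k in attrs), "protein_coding"
                )
                meta[gene_id] = {"biotype": biotype, "span": None}
            if feature == "gene":
                meta[gene_id]["span"] = iv
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id in order:
        exs = sorted(exons.get(gene_id, []), key=lambda x: x.start)
        span = meta[gene_id]["span"]
        if span is None:
            if not exs:
                continue
            span = GenomicInterval(exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand)
        genes.append(GeneModel(gene_id, span, tuple(exs), meta[gene_id]["biotype"]))
    return genes


def write_gene_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            iv = gene.interval
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                f"{iv.chrom}\tl1ll\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for k, ex in enumerate(gene.exons, start=1):
                ex_attrs = attrs + f' exon_number "{k}";'
                fh.write(
                    f"{ex.chrom}\tl1ll\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{ex_attrs}\n"
                )


def write_promoter_bed(promoters: Iterable[PromoterWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prom in promoters:
            iv = prom.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{prom.locus_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# operations


def select_full_length_young(
    loci: Sequence[TELocus],
    min_length: int = FULL_LENGTH_BP,
    subfamilies: frozenset[str] | set[str] = YOUNG_SUBFAMILIES,
) -> list[TELocus]:
    """Full-length (> ``min_length`` bp, strict) young-subfamily loci, input order kept."""
    return [
        locus
        for locus in loci
        if locus.length > min_length and locus.subfamily in subfamilies
    ]


def promoter_window(locus: TELocus, span: int = PROMOTER_SPAN_BP) -> PromoterWindow:
    """The first ``span`` bp from the element 5' end, clipped to the element.

    Plus-strand elements start at ``interval.start``; minus-strand elements
    start at ``interval.end`` and run leftwards.
    """
    iv = locus.interval
    if iv.strand not in ("+", "-"):
        raise ValueError(f"{locus.locus_id}: promoter window requires an oriented locus")
    eff = min(span, iv.length)
    if iv.strand == "+":
        win = GenomicInterval(iv.chrom, iv.start, iv.start + eff, iv.strand)
    else:
        win = GenomicInterval(iv.chrom, iv.end - eff, iv.end, iv.strand)
    return PromoterWindow(locus.locus_id, win, eff)


def nearest_feature_distance(
    gene: GeneModel,
    loci: Sequence[TELocus],
    cutoff: int = 50_000,
) -> NearestFeature:
    """Distance from a gene body to the nearest locus, with a distance bin.

    Returns distance 0 and the ``intragenic`` bin when any locus overlaps
    the gene interval; otherwise the minimal edge-to-edge gap to any
    same-chromosome locus. Ties are broken by smaller locus start, then
    lexicographic locus id. Genes with no same-chromosome locus get
    distance ``inf`` and the beyond-cutoff bin.
    """
    if not loci:
        raise ValueError("loci list must be non-empty")
    giv = gene.interval
    # key: distance, overlap beats zero-gap adjacency, smaller start, lexicographic id
    best: tuple[float, int, int, str] | None = None
    for locus in loci:
        liv = locus.interval
        if liv.chrom != giv.chrom:
            continue
        if overlap_length(giv, liv) > 0:
            dist, no_overlap = 0.0, 0
        else:
            dist = float(max(liv.start - giv.end, giv.start - liv.end, 0))
            no_overlap = 1
        key = (dist, no_overlap, liv.start, locus.locus_id)
        if best is None or key < best:
            best = key
    if best is None:
        return NearestFeature(math.inf, None, BIN_BEYOND)
    dist, no_overlap, _, locus_id = best
    if dist == 0 and not no_overlap:
        return NearestFeature(0.0, locus_id, BIN_INTRAGENIC)
    bin_ = BIN_WITHIN if dist <= cutoff else BIN_BEYOND
    return NearestFeature(dist, locus_id, bin_)


def classify_genomic_context(
    locus: TELocus, genes: Sequence[GeneModel]
) -> str:
    """Classify a locus as intergenic or intragenic sense/antisense.

    A locus overlapping at least one gene body is intragenic; orientation
    is judged against the host gene with the largest overlap (ties: smaller
    gene start, then gene id). Most expressed L1s sit in intergenic
    regions; intragenic ones typically transcribe opposite their host.
    """
    if locus.interval.strand not in ("+", "-"):
        raise ValueError(f"{locus.locus_id}: context classification requires an oriented locus")
    best: tuple[int, int, str] | None = None
    host: GeneModel | None = None
    for gene in genes:
        ov = overlap_length(locus.interval, gene.interval)
        if ov <= 0:
            continue
        key = (-ov, gene.interval.start, gene.gene_id)
        if best is None or key < best:
            best = key
            host = gene
    if host is None:
        return "intergenic"
    if host.strand == locus.interval.strand:
        return "intragenic_sense"
    return "intragenic_antisense"
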