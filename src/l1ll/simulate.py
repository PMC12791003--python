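"""Seeded synthetic-data generator with planted ground truth.

Generates a self-consistent toy dataset exercising every pipeline stage:
a small genome with planted full-length young L1 loci (expressed and
hypomethylated vs silent and methylated) plus shorter/older decoy copies,
genes with exon chains including cis-regulated genes whose downstream
exons are driven by an intronic antisense L1, negative-binomial stranded
fragment counts with CRISPRi silencing of targeted loci, beta-binomial
CpG methylation calls, H3K4me3/dCas9 peak sets with a shared technical
artifact class, DE tables derived from the planted effects, clustered
barcoded single-cell reads, and two-condition organoid growth curves.

Everything is deterministic given the configuration seed. Fragments are
placed uniformly within features (no positional bias is modeled) and no
sequence-level simulation is performed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import (
    GeneModel,
    TELocus,
    promoter_window,
    select_full_length_young,
    write_gene_gtf,
    write_te_gtf,
)
from .epigenome import Peak, write_peaks_bed
from .intervals import GenomicInterval
from .methylation import write_cpg_calls
from .quantify import READ_COLUMNS, write_read_table
from .phenotype import write_area_table
from .cis import write_de_table

CONDITION_CONTROL = "control"
CONDITION_CRISPRI = "crispri"

_YOUNG = ("L1HS", "L1PA2", "L1PA3", "L1PA4")
_OLD = ("L1PA7", "L1PA8", "L1PA10", "L1PA13", "L1MA4")

# distinct sub-stream keys so each component is independently reproducible
_STREAMS = {
    "annotation": 1,
    "reads": 2,
    "methylation": 3,
    "peaks": 4,
    "de": 5,
    "sc": 6,
    "areas": 7,
    "metrics": 8,
}


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic dataset.

    The default scale (2 chromosomes x 5 Mb, 200 L1 loci, 300 genes, 3+3
    bulk samples, 50k fragments per sample) keeps a full pipeline run in
    seconds on one CPU while preserving the data structure of the study.
    """

    seed: int = 0
    # genome & annotation
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_l1_loci: int = 200
    frac_full_length_young: float = 0.5
    n_genes: int = 300
    n_cis_genes: int = 50
    expressed_fraction: float = 0.6
    # bulk reads
    n_samples_per_condition: int = 3
    mean_depth: int = 50_000
    nb_dispersion: float = 0.1
    silencing_efficiency: float = 0.9
    multimap_fraction: float = 0.05
    fragment_length: int = 300
    depth_jitter: float = 0.2
    # methylation
    meth_high: float = 85.0
    meth_low: float = 10.0
    cpg_spacing: int = 50
    meth_coverage: int = 10
    meth_concentration: float = 20.0
    meth_samples: tuple[str, ...] = ("hiPSC1", "hiPSC2")
    # peaks
    n_background_peaks: int = 25
    n_shared_dcas9_peaks: int = 30
    peak_width: int = 400
    # DE tables
    de_noise_sd: float = 0.2
    de_comparisons: tuple[str, ...] = ("line1_g1", "line1_g2", "line2_g1")
    de_null_lfc_sd: float = 0.1
    # single cell
    cluster_count: int = 4
    cells_per_cluster: int = 50
    sc_depth: int = 20_000
    sc_private_cluster: int = 2
    # organoid growth
    n_organoids: int = 20
    n_batches: int = 1
    area_day0: float = 1.0e4
    control_growth: float = 1.2
    treatment_growth: float = 1.1
    divergence_day: int = 10
    area_sigma: float = 0.10
    measurement_days: tuple[int, ...] = (2, 5, 9, 12, 15)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("meth_samples", "de_comparisons", "measurement_days"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted labels used as the oracle in recovery tests."""

    expressed_loci: set[str]
    silent_fl_loci: set[str]
    targeted_loci: set[str]
    decoy_loci: set[str]
    locus_weight: dict[str, float]
    gene_weight: dict[str, float]
    cis_genes: dict[str, dict]
    locus_meth_percent: dict[str, float]
    private_locus: str | None = None
    private_cluster: int = 2

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("expressed_loci", "silent_fl_loci", "targeted_loci", "decoy_loci"):
            data[key] = sorted(data[key])
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("expressed_loci", "silent_fl_loci", "targeted_loci", "decoy_loci"):
            data[key] = set(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[TELocus], list[GeneModel], GroundTruth]:
    """Place loci and genes into non-overlapping slots and plant the truth.

    Full-length young loci (> 6 kb, L1HS-L1PA4) are planted alongside
    shorter/older decoys; each cis gene hosts one expressed, targeted L1 in
    antisense orientation inside the intron separating its lowly-expressed
    canonical upstream exons from its highly-expressed downstream exons.
    """
    rng = cfg.rng("annotation")
    n_fl = round(cfg.n_l1_loci * cfg.frac_full_length_young)
    n_cis = min(cfg.n_cis_genes, n_fl, cfg.n_genes)
    n_standalone_fl = n_fl - n_cis
    n_decoys = cfg.n_l1_loci - n_fl
    n_plain_genes = cfg.n_genes - n_cis

    units = (
        ["cis"] * n_cis
        + ["fl"] * n_standalone_fl
        + ["decoy"] * n_decoys
        + ["gene"] * n_plain_genes
    )
    rng.shuffle(units)
    n_units = len(units)
    units_per_chrom = math.ceil(n_units / cfg.n_chroms)
    slot_w = cfg.chrom_length // max(units_per_chrom, 1)
    max_unit = 15_000
    if slot_w <= max_unit:
        raise ValueError(
            f"chromosomes too small: slot width {slot_w} bp cannot hold a "
            f"{max_unit} bp unit; increase chrom_length to at least "
            f"{(max_unit + 1) * units_per_chrom} bp or reduce feature counts"
        )

    loci: list[TELocus] = []
    genes: list[GeneModel] = []
    locus_counter = 0
    gene_counter = 0
    cis_genes: dict[str, dict] = {}
    cis_driver_ids: list[str] = []
    standalone_fl_ids: list[str] = []
    decoy_ids: list[str] = []

    def _strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    for k, unit in enumerate(units):
        chrom = f"chr{k // units_per_chrom + 1}"
        base = (k % units_per_chrom) * slot_w

        if unit in ("fl", "decoy"):
            if unit == "fl":
                length = int(rng.integers(6001, 7501))
                subfam = str(rng.choice(_YOUNG))
            elif rng.random() < 0.5:  # short young decoy
                length = int(rng.integers(1500, 6000))
                subfam = str(rng.choice(_YOUNG))
            else:  # long old decoy
                length = int(rng.integers(6001, 7001))
                subfam = str(rng.choice(_OLD))
            start = base + int(rng.integers(0, slot_w - length))
            locus_counter += 1
            locus = TELocus(
                f"L1_{locus_counter:04d}",
                GenomicInterval(chrom, start, start + length, _strand()),
                subfam,
            )
            loci.append(locus)
            if unit == "fl":
                standalone_fl_ids.append(locus.locus_id)
            else:
                decoy_ids.append(locus.locus_id)
            continue

        gene_counter += 1
        gene_id = f"gene_{gene_counter:04d}"
        strand = _strand()
        if unit == "gene":
            n_exons = int(rng.integers(2, 6))
            exon_lens = rng.integers(200, 1201, size=n_exons)
            intron_lens = rng.integers(400, 1501, size=max(n_exons - 1, 0))
            total = int(exon_lens.sum() + intron_lens.sum())
            start = base + int(rng.integers(0, slot_w - total))
            exons = []
            pos = start
            for i in range(n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            interval = GenomicInterval(chrom, start, pos, strand)
            biotype = str(
                rng.choice(["protein_coding", "lncRNA", "other"], p=[0.6, 0.3, 0.1])
            )
            genes.append(GeneModel(gene_id, interval, tuple(exons), biotype))
            continue

        # cis gene: 2 canonical upstream exons | intron hosting antisense L1 |
        # 3 L1-driven downstream exons (in transcript orientation)
        l1_len = int(rng.integers(6001, 7001))
        up_lens = rng.integers(300, 801, size=2)
        down_lens = rng.integers(300, 801, size=3)
        small_introns = rng.integers(300, 801, size=3)
        pad = 200
        total = int(up_lens.sum() + down_lens.sum() + small_introns.sum() + 2 * pad + l1_len)
        start = base + int(rng.integers(0, slot_w - total))
        # genomic layout in transcript order, then mirror for minus strand
        blocks: list[tuple[str, int]] = [
            ("exon", int(up_lens[0])),
            ("intron", int(small_introns[0])),
            ("exon", int(up_lens[1])),
            ("pad", pad),
            ("l1", l1_len),
            ("pad", pad),
            ("exon", int(down_lens[0])),
            ("intron", int(small_introns[1])),
            ("exon", int(down_lens[1])),
            ("intron", int(small_introns[2])),
            ("exon", int(down_lens[2])),
        ]
        if strand == "-":
            blocks = blocks[::-1]
        exons = []
        l1_iv = None
        pos = start
        for kind, width in blocks:
            if kind == "exon":
                exons.append(GenomicInterval(chrom, pos, pos + width, strand))
            elif kind == "l1":
                # antisense to the host gene
                l1_strand = "-" if strand == "+" else "+"
                l1_iv = GenomicInterval(chrom, pos, pos + width, l1_strand)
            pos += width
        interval = GenomicInterval(chrom, start, pos, strand)
        biotype = str(rng.choice(["lncRNA", "protein_coding"], p=[0.67, 0.33]))
        genes.append(GeneModel(gene_id, interval, tuple(exons), biotype))
        locus_counter += 1
        driver = TELocus(
            f"L1_{locus_counter:04d}", l1_iv, str(rng.choice(_YOUNG))
        )
        loci.append(driver)
        cis_driver_ids.append(driver.locus_id)
        cis_genes[gene_id] = {
            "driver_locus_id": driver.locus_id,
            "planted_log2fc": float(np.log2(max(1.0 - cfg.silencing_efficiency, 2**-8))),
        }

    # planted expression labels
    n_expr = max(n_cis, round(n_fl * cfg.expressed_fraction))
    extra = n_expr - n_cis
    chosen = list(
        rng.choice(standalone_fl_ids, size=min(extra, len(standalone_fl_ids)), replace=False)
    )
    expressed = set(cis_driver_ids) | set(chosen)
    fl_ids = set(cis_driver_ids) | set(standalone_fl_ids)
    silent = fl_ids - expressed

    locus_weight: dict[str, float] = {}
    for locus in loci:
        if locus.locus_id in expressed:
            locus_weight[locus.locus_id] = float(rng.lognormal(np.log(0.5), 0.6))
        elif locus.locus_id in silent:
            locus_weight[locus.locus_id] = 1e-4
        else:  # decoys: trace-level background
            locus_weight[locus.locus_id] = float(10 ** rng.uniform(-4, -2.5))

    gene_weight: dict[str, float] = {}
    for gene in genes:
        if gene.gene_id in cis_genes:
            down_w = float(rng.lognormal(np.log(0.8), 0.4))
            cis_genes[gene.gene_id]["downstream_weight"] = down_w
            cis_genes[gene.gene_id]["upstream_weight"] = down_w * 0.05
        else:
            gene_weight[gene.gene_id] = float(rng.lognormal(0.0, 0.7))

    meth: dict[str, float] = {}
    for locus_id in fl_ids:
        level = cfg.meth_low if locus_id in expressed else cfg.meth_high
        if 0.0 < level < 100.0:  # keep the fully (un)methylated limit cases exact
            level = float(np.clip(level + rng.uniform(-5, 5), 0, 100))
        meth[locus_id] = float(level)

    private = None
    pool = sorted(str(x) for x in chosen) or sorted(expressed)
    if pool:
        private = str(pool[0])

    truth = GroundTruth(
        expressed_loci=expressed,
        silent_fl_loci=silent,
        targeted_loci=set(expressed),
        decoy_loci=set(decoy_ids),
        locus_weight=locus_weight,
        gene_weight=gene_weight,
        cis_genes=cis_genes,
        locus_meth_percent=meth,
        private_locus=private,
        private_cluster=cfg.sc_private_cluster,
    )
    return loci, genes, truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class _Unit:
    segments: list[GenomicInterval]  # where fragments may start
    strand: str
    weight_control: float
    weight_crispri: float


def _emission_units(
    loci: Sequence[TELocus],
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> list[_Unit]:
    eff = cfg.silencing_efficiency
    units: list[_Unit] = []
    for locus in loci:
        w = truth.locus_weight[locus.locus_id]
        w_t = w * (1.0 - eff) if locus.locus_id in truth.targeted_loci else w
        units.append(_Unit([locus.interval], locus.interval.strand, w, w_t))
    for gene in genes:
        if gene.gene_id in truth.cis_genes:
            info = truth.cis_genes[gene.gene_id]
            driver = info["driver_locus_id"]
            l1 = next(l for l in loci if l.locus_id == driver)
            if gene.strand == "+":
                upstream = [ex for ex in gene.exons if ex.end <= l1.interval.start]
                downstream = [ex for ex in gene.exons if ex.start >= l1.interval.end]
            else:
                upstream = [ex for ex in gene.exons if ex.start >= l1.interval.end]
                downstream = [ex for ex in gene.exons if ex.end <= l1.interval.start]
            up_w = info["upstream_weight"]
            down_w = info["downstream_weight"]
            units.append(_Unit(upstream, gene.strand, up_w, up_w))
            units.append(_Unit(downstream, gene.strand, down_w, down_w * (1.0 - eff)))
        else:
            w = truth.gene_weight[gene.gene_id]
            units.append(_Unit(list(gene.exons), gene.strand, w, w))
    return units


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2."""
    counts = np.zeros(means.shape, dtype=np.int64)
    pos = means > 0
    if pos.any():
        if dispersion <= 0:
            counts[pos] = rng.poisson(means[pos])
        else:
            n = 1.0 / dispersion
            p = n / (n + means[pos])
            counts[pos] = rng.negative_binomial(n, p)
    return counts


def _place_fragments(
    rng: np.random.Generator,
    unit: _Unit,
    count: int,
    sample_id: str,
    frag_len: int,
    out: list,
) -> None:
    seg_lens = np.array([s.length for s in unit.segments], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_lens)])
    offsets = rng.integers(0, cum[-1], size=count)
    seg_idx = np.searchsorted(cum, offsets, side="right") - 1
    within = offsets - cum[seg_idx]
    starts = np.array([s.start for s in unit.segments], dtype=np.int64)[seg_idx] + within
    seg_ends = np.array([s.end for s in unit.segments], dtype=np.int64)[seg_idx]
    ends = np.minimum(starts + frag_len, seg_ends)
    chrom = unit.segments[0].chrom
    out.append(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "strand": unit.strand,
                "sample_id": sample_id,
                "unique": True,
                "barcode": pd.NA,
            }
        )
    )


def simulate_reads(
    loci: Sequence[TELocus],
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    condition: str,
) -> pd.DataFrame:
    """Bulk fragment table for one condition (all replicate samples).

    Per-feature fragment counts are negative-binomial with mean
    proportional to the planted expression, the per-sample depth factor
    and, for CRISPRi, the silencing factor on targeted loci and the
    L1-driven downstream exon blocks of cis genes. Fragments are placed
    uniformly within features on the transcribed strand; a configurable
    fraction of multi-mapping decoy fragments is emitted with
    ``unique=False``.
    """
    if condition not in (CONDITION_CONTROL, CONDITION_CRISPRI):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        [int(cfg.seed), _STREAMS["reads"], 0 if condition == CONDITION_CONTROL else 1]
    )
    units = _emission_units(loci, genes, truth, cfg)
    units = [u for u in units if u.segments]
    w_ctrl = np.array([u.weight_control for u in units])
    w_cond = np.array(
        [
            u.weight_control if condition == CONDITION_CONTROL else u.weight_crispri
            for u in units
        ]
    )
    scale = cfg.mean_depth / w_ctrl.sum() if w_ctrl.sum() > 0 else 0.0
    frames: list[pd.DataFrame] = []
    for rep in range(cfg.n_samples_per_condition):
        sample_id = f"{condition}_rep{rep + 1}"
        depth_factor = 1.0 + rng.uniform(-cfg.depth_jitter, cfg.depth_jitter)
        means = w_cond * scale * depth_factor
        counts = _nb_counts(rng, means, cfg.nb_dispersion)
        for u_idx in np.flatnonzero(counts):
            _place_fragments(
                rng, units[u_idx], int(counts[u_idx]), sample_id,
                cfg.fragment_length, frames,
            )
        n_multi = int(rng.poisson(cfg.mean_depth * depth_factor * cfg.multimap_fraction))
        if n_multi:
            chroms = rng.integers(1, cfg.n_chroms + 1, size=n_multi)
            starts = rng.integers(0, cfg.chrom_length - cfg.fragment_length, size=n_multi)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": [f"chr{c}" for c in chroms],
                        "start": starts,
                        "end": starts + cfg.fragment_length,
                        "strand": rng.choice(["+", "-"], size=n_multi),
                        "sample_id": sample_id,
                        "unique": False,
                        "barcode": pd.NA,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=READ_COLUMNS)
    reads = pd.concat(frames, ignore_index=True)
    return reads[READ_COLUMNS]


def simulate_single_cell_reads(
    loci: Sequence[TELocus],
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    condition: str = CONDITION_CONTROL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcoded reads plus a barcode-to-cluster assignment table.

    Reuses the bulk fragment model per cluster; the planted
    cluster-private locus emits fragments only in cluster
    ``truth.private_cluster``. Returns ``(reads, assignment)``.
    """
    rng = np.random.default_rng(
        [int(cfg.seed), _STREAMS["sc"], 0 if condition == CONDITION_CONTROL else 1]
    )
    sample_id = f"{condition}_sc"
    units = _emission_units(loci, genes, truth, cfg)
    units = [u for u in units if u.segments]
    # map locus units by id for private-cluster zeroing
    locus_unit_idx = {
        loci[i].locus_id: i for i in range(len(loci)) if loci[i].interval.length > 0
    }
    w_base = np.array(
        [
            u.weight_control if condition == CONDITION_CONTROL else u.weight_crispri
            for u in units
        ]
    )
    scale = (cfg.sc_depth / cfg.cluster_count) / w_base.sum()
    frames: list[pd.DataFrame] = []
    assign_rows = []
    for cluster in range(cfg.cluster_count):
        barcodes = [f"BC{cluster}_{i:04d}" for i in range(cfg.cells_per_cluster)]
        for bc in barcodes:
            assign_rows.append((bc, sample_id, f"cluster_{cluster}"))
        w = w_base.copy()
        if truth.private_locus is not None:
            idx = locus_unit_idx[truth.private_locus]
            if cluster != truth.private_cluster:
                w[idx] = 0.0
            else:
                w[idx] = max(w[idx], 0.5)  # clearly detectable in its home cluster
        means = w * scale
        counts = _nb_counts(rng, means, cfg.nb_dispersion)
        cluster_frames: list[pd.DataFrame] = []
        for u_idx in np.flatnonzero(counts):
            _place_fragments(
                rng, units[u_idx], int(counts[u_idx]), sample_id,
                cfg.fragment_length, cluster_frames,
            )
        if cluster_frames:
            block = pd.concat(cluster_frames, ignore_index=True)
            block["barcode"] = rng.choice(barcodes, size=len(block))
            frames.append(block)
    assignment = pd.DataFrame(
        assign_rows, columns=["barcode", "sample_id", "cluster_id"]
    )
    if not frames:
        return pd.DataFrame(columns=READ_COLUMNS), assignment
    reads = pd.concat(frames, ignore_index=True)[READ_COLUMNS]
    return reads, assignment


# ---------------------------------------------------------------------------
# methylation, peaks, DE tables, growth, QC metrics


def simulate_methylation(
    loci: Sequence[TELocus],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Per-read CpG calls over full-length-young promoter windows.

    CpG sites sit every ``cpg_spacing`` bp in the promoter; each read's
    methylation probability is beta-binomial around the planted per-locus
    level (hypomethylated when expressed, methylated when silent).
    """
    rng = cfg.rng("methylation")
    fl = select_full_length_young(loci)
    rows_chrom, rows_pos, rows_read, rows_state, rows_sample = [], [], [], [], []
    conc = cfg.meth_concentration
    for locus in fl:
        prom = promoter_window(locus)
        sites = np.arange(prom.interval.start, prom.interval.end, cfg.cpg_spacing)
        level = truth.locus_meth_percent.get(locus.locus_id, cfg.meth_high) / 100.0
        for sample in cfg.meth_samples:
            n_reads = max(1, int(rng.poisson(cfg.meth_coverage)))
            for r in range(n_reads):
                if level <= 0.0:
                    p_read = 0.0
                elif level >= 1.0:
                    p_read = 1.0
                else:
                    p_read = rng.beta(level * conc, (1.0 - level) * conc)
                states = (rng.random(sites.size) < p_read).astype(int)
                read_id = f"{locus.locus_id}_{sample}_r{r}"
                rows_chrom.extend([prom.interval.chrom] * sites.size)
                rows_pos.extend(sites.tolist())
                rows_read.extend([read_id] * sites.size)
                rows_state.extend(states.tolist())
                rows_sample.extend([sample] * sites.size)
    return pd.DataFrame(
        {
            "chrom": rows_chrom,
            "pos": rows_pos,
            "read_id": rows_read,
            "state": rows_state,
            "sample_id": rows_sample,
        }
    )


def _random_clear_interval(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    avoid: Sequence[GenomicInterval],
    width: int,
    margin: int = 300,
) -> GenomicInterval:
    """A random interval keeping ``margin`` bp clear of the avoided set,
    so flank-expanded peak comparisons cannot graze it."""
    for _ in range(1000):
        chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        start = int(rng.integers(0, cfg.chrom_length - width))
        iv = GenomicInterval(chrom, start, start + width, ".")
        if not any(
            a.chrom == iv.chrom
            and min(a.end + margin, iv.end) > max(a.start - margin, iv.start)
            for a in avoid
        ):
            return iv
    raise RuntimeError("could not place a background interval clear of annotations")


def simulate_peaks(
    loci: Sequence[TELocus],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> dict[str, list[Peak]]:
    """H3K4me3 and dCas9 peak sets consistent with the planted truth.

    H3K4me3 peaks cover every expressed locus promoter (plus optional
    background peaks clear of young L1s); dCas9 treatment peaks sit at the
    5' end of every targeted locus, and a set of shared technical peaks is
    present in both the treatment and the control peak set (the artifact
    class removed by the control filter).
    """
    rng = cfg.rng("peaks")
    fl = select_full_length_young(loci)
    fl_ivs = [l.interval for l in fl]
    h3k4me3: list[Peak] = []
    for locus in fl:
        if locus.locus_id not in truth.expressed_loci:
            continue
        prom = promoter_window(locus)
        mid = (prom.interval.start + prom.interval.end) // 2
        half = cfg.peak_width // 2
        iv = GenomicInterval(
            prom.interval.chrom, max(0, mid - half), mid + half, "."
        )
        h3k4me3.append(
            Peak(f"k4_{locus.locus_id}", iv, float(rng.uniform(1e-6, 0.049)))
        )
    for b in range(cfg.n_background_peaks):
        iv = _random_clear_interval(rng, cfg, fl_ivs, cfg.peak_width)
        h3k4me3.append(Peak(f"k4_bg_{b:03d}", iv, float(rng.uniform(1e-4, 0.2))))

    treatment: list[Peak] = []
    control: list[Peak] = []
    for locus in fl:
        if locus.locus_id not in truth.targeted_loci:
            continue
        site = promoter_window(locus, span=200)
        iv = GenomicInterval(
            site.interval.chrom, site.interval.start, site.interval.end, "."
        )
        treatment.append(
            Peak(f"dcas9_{locus.locus_id}", iv, float(rng.uniform(1e-6, 0.01)))
        )
    locus_ivs = [l.interval for l in loci]
    for s in range(cfg.n_shared_dcas9_peaks):
        iv = _random_clear_interval(rng, cfg, locus_ivs, cfg.peak_width)
        p = float(rng.uniform(1e-6, 0.04))
        treatment.append(Peak(f"dcas9_shared_t_{s:03d}", iv, p))
        control.append(Peak(f"dcas9_shared_c_{s:03d}", iv, p))
    return {
        "h3k4me3": h3k4me3,
        "dcas9_treatment": treatment,
        "dcas9_control": control,
    }


def simulate_de_tables(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Per-comparison DE tables derived from the planted cis effects.

    Cis-driven genes carry their planted negative log2FC plus noise and a
    significant adjusted p; all other genes draw from a null. The first
    comparison id is the base comparison of the consistency rule.
    """
    rng = cfg.rng("de")
    tables: dict[str, pd.DataFrame] = {}
    gene_ids = [g.gene_id for g in genes]
    for comparison in cfg.de_comparisons:
        lfc = rng.normal(0.0, cfg.de_null_lfc_sd, size=len(gene_ids))
        padj = rng.uniform(0.06, 1.0, size=len(gene_ids))
        for i, gene_id in enumerate(gene_ids):
            if gene_id in truth.cis_genes:
                lfc[i] = truth.cis_genes[gene_id]["planted_log2fc"] + rng.normal(
                    0.0, cfg.de_noise_sd
                )
                padj[i] = rng.uniform(1e-6, 0.01)
        tables[comparison] = pd.DataFrame(
            {"gene_id": gene_ids, "log2fc": lfc, "padj": padj}
        )
    return tables


def plant_de_table(
    n_genes: int = 1000,
    n_down: int = 99,
    n_up: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """A standalone DE table with exactly planted down/up gene sets.

    Down genes get log2FC <= -1 and significant padj, up genes mirrored,
    and null genes a non-significant padj, so a threshold classification
    recovers the planted sets exactly.
    """
    if n_down + n_up > n_genes:
        raise ValueError("planted genes exceed table size")
    rng = np.random.default_rng([seed, 97])
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    labels = np.array(["down"] * n_down + ["up"] * n_up + ["ns"] * (n_genes - n_down - n_up))
    rng.shuffle(labels)
    lfc = rng.normal(0.0, 0.3, size=n_genes)
    padj = rng.uniform(0.051, 1.0, size=n_genes)
    down_mask = labels == "down"
    up_mask = labels == "up"
    lfc[down_mask] = -(1.0 + rng.exponential(1.0, size=down_mask.sum()))
    lfc[up_mask] = 1.0 + rng.exponential(1.0, size=up_mask.sum())
    padj[down_mask | up_mask] = rng.uniform(1e-8, 0.049, size=int((down_mask | up_mask).sum()))
    table = pd.DataFrame({"gene_id": gene_ids, "log2fc": lfc, "padj": padj})
    truth = {
        "down": set(np.array(gene_ids)[down_mask]),
        "up": set(np.array(gene_ids)[up_mask]),
    }
    return table, truth


def simulate_areas(cfg: SimulationConfig) -> pd.DataFrame:
    """Organoid area measurements with post-divergence growth slowdown.

    Both conditions grow at ``control_growth`` per day until
    ``divergence_day``; afterwards the treatment condition grows at
    ``treatment_growth``. Areas carry multiplicative log-normal noise.
    """
    rng = cfg.rng("areas")
    rows = []
    for b in range(cfg.n_batches):
        batch = f"batch{b + 1}"
        for condition, late_growth in (
            ("control", cfg.control_growth),
            ("treatment", cfg.treatment_growth),
        ):
            for i in range(cfg.n_organoids):
                organoid = f"{batch}_{condition}_{i:02d}"
                for day in cfg.measurement_days:
                    early = min(day, cfg.divergence_day)
                    late = max(0, day - cfg.divergence_day)
                    mean = (
                        cfg.area_day0
                        * cfg.control_growth**early
                        * late_growth**late
                    )
                    area = float(mean * np.exp(rng.normal(0.0, cfg.area_sigma)))
                    rows.append((organoid, condition, batch, int(day), area))
    return pd.DataFrame(rows, columns=["organoid_id", "condition", "batch", "day", "area"])


def simulate_cell_metrics(
    cfg: SimulationConfig,
    n_cells: int = 200,
    sample_id: str = "control_sc",
    n_mito_outliers: int = 4,
    n_high_outliers: int = 3,
    n_low_outliers: int = 3,
    barcodes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-cell QC metrics with planted outliers.

    Core cells have tightly clustered feature counts and low mitochondrial
    content; planted outliers are far outside the QC bounds, so single-pass
    mean/SD filtering removes exactly them. Returns ``(metrics,
    outlier_barcodes)``.
    """
    rng = cfg.rng("metrics")
    n_out = n_mito_outliers + n_high_outliers + n_low_outliers
    if n_out >= n_cells:
        raise ValueError("more outliers than cells")
    if barcodes is None:
        barcodes = [f"BC_{i:04d}" for i in range(n_cells)]
    elif len(barcodes) != n_cells:
        raise ValueError("barcodes length must equal n_cells")
    n_core = n_cells - n_out
    features = np.concatenate(
        [
            rng.integers(1900, 2101, size=n_core),
            rng.integers(1900, 2101, size=n_mito_outliers),
            rng.integers(5900, 6101, size=n_high_outliers),
            rng.integers(150, 251, size=n_low_outliers),
        ]
    )
    mito = np.concatenate(
        [
            rng.uniform(0, 5, size=n_core),
            rng.uniform(12, 20, size=n_mito_outliers),
            rng.uniform(0, 5, size=n_high_outliers + n_low_outliers),
        ]
    )
    metrics = pd.DataFrame(
        {
            "barcode": list(barcodes),
            "sample_id": sample_id,
            "n_features": features,
            "percent_mito": mito,
        }
    )
    outliers = set(list(barcodes)[n_core:])
    return metrics, outliers


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset and write it as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci, genes, truth = simulate_annotation(cfg)
    paths: dict[str, Path] = {}

    paths["te_gtf"] = outdir / "te.gtf"
    write_te_gtf(loci, paths["te_gtf"])
    paths["genes_gtf"] = outdir / "genes.gtf"
    write_gene_gtf(genes, paths["genes_gtf"])

    bulk = pd.concat(
        [
            simulate_reads(loci, genes, truth, cfg, CONDITION_CONTROL),
            simulate_reads(loci, genes, truth, cfg, CONDITION_CRISPRI),
        ],
        ignore_index=True,
    )
    paths["reads_bulk"] = outdir / "reads_bulk.tsv"
    write_read_table(bulk, paths["reads_bulk"])

    sc_reads, assignment = simulate_single_cell_reads(loci, genes, truth, cfg)
    paths["reads_sc"] = outdir / "reads_sc.tsv"
    write_read_table(sc_reads, paths["reads_sc"])
    paths["clusters"] = outdir / "clusters.tsv"
    assignment.to_csv(paths["clusters"], sep="\t", index=False)

    n_sc_cells = cfg.cluster_count * cfg.cells_per_cluster
    metrics, _ = simulate_cell_metrics(
        cfg,
        n_cells=n_sc_cells,
        sample_id=f"{CONDITION_CONTROL}_sc",
        n_mito_outliers=0,
        n_high_outliers=0,
        n_low_outliers=0,
        barcodes=list(assignment["barcode"]),
    )
    paths["qc_metrics"] = outdir / "qc_metrics.tsv"
    metrics.to_csv(paths["qc_metrics"], sep="\t", index=False)

    calls = simulate_methylation(loci, truth, cfg)
    paths["methylation"] = outdir / "methylation.tsv"
    write_cpg_calls(calls, paths["methylation"])

    peaks = simulate_peaks(loci, truth, cfg)
    for name, plist in peaks.items():
        paths[f"peaks_{name}"] = outdir / f"peaks_{name}.bed"
        write_peaks_bed(plist, paths[f"peaks_{name}"])

    for comparison, table in simulate_de_tables(genes, truth, cfg).items():
        paths[f"de_{comparison}"] = outdir / f"de_{comparison}.tsv"
        write_de_table(table, paths[f"de_{comparison}"])

    areas = simulate_areas(cfg)
    paths["areas"] = outdir / "areas.tsv"
    write_area_table(areas, paths["areas"])

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
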