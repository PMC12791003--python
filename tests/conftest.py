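from __future__ import annotations

import numpy as np
import pytest

from l1ll.annotations import GeneModel, TELocus
from l1ll.intervals import GenomicInterval
from l1ll.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A scaled-down generator configuration for fast fixtures."""
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        n_l1_loci=20,
        frac_full_length_young=0.5,
        n_genes=20,
        n_cis_genes=5,
        mean_depth=6_000,
        cluster_count=3,
        cells_per_cluster=20,
        sc_depth=9_000,
        n_background_peaks=5,
        n_shared_dcas9_peaks=5,
        meth_coverage=6,
    )


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return simulate_annotation(small_cfg)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 10_000, max_len: int = 500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + length,
                str(rng.choice(["+", "-", "."])),
            )
        )
    return out


def random_loci(rng: np.random.Generator, n: int, **kw) -> list[TELocus]:
    ivs = random_intervals(rng, n, **kw)
    return [
        TELocus(
            f"L1_{i:03d}",
            GenomicInterval(iv.chrom, iv.start, iv.end, str(rng.choice(["+", "-"]))),
            str(rng.choice(["L1HS", "L1PA2", "L1PA3", "L1PA4", "L1PA7"])),
        )
        for i, iv in enumerate(ivs)
    ]


def random_genes(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 max_pos: int = 10_000) -> list[GeneModel]:
    genes = []
    for i in range(n):
        chrom = str(rng.choice(chroms))
        strand = str(rng.choice(["+", "-"]))
        pos = int(rng.integers(0, max_pos))
        exons = []
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(50, 400))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(20, 200))
        interval = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        genes.append(GeneModel(f"gene_{i:03d}", interval, tuple(exons)))
    return genes
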