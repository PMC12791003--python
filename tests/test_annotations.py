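import math

import numpy as np
import pytest

from l1ll.annotations import (
    GeneModel,
    TELocus,
    classify_genomic_context,
    nearest_feature_distance,
    promoter_window,
    read_gene_annotation,
    read_te_annotation,
    select_full_length_young,
    write_gene_gtf,
    write_te_bed,
    write_te_gtf,
)
from l1ll.intervals import GenomicInterval

from conftest import random_genes, random_loci
from oracles import brute_nearest


def _locus(start, end, strand="+", subfam="L1HS", locus_id="L1_x"):
    return TELocus(locus_id, GenomicInterval("chr1", start, end, strand), subfam)


def _gene(start, end, strand="+", gene_id="g", chrom="chr1"):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id, iv, (iv,))


class TestReadTEAnnotation:
    def test_gtf_converts_to_zero_based_half_open(self, tmp_path):
        path = tmp_path / "te.gtf"
        path.write_text(
            'chr1\trmsk\texon\t1001\t8000\t.\t-\t.\tgene_id "L1HS"; '
            'transcript_id "L1HS_dup1"; family_id "L1"; class_id "LINE";\n'
        )
        (locus,) = read_te_annotation(path)
        assert (locus.interval.start, locus.interval.end) == (1000, 8000)
        assert locus.interval.strand == "-"
        assert locus.subfamily == "L1HS"
        assert locus.locus_id == "L1HS_dup1"

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_te_annotation(path) == []

    def test_bed_fixture_parses_subfamilies(self, tmp_path):
        path = tmp_path / "te.bed"
        path.write_text(
            "chr1\t100\t7000\tL1HS\t0\t+\n"
            "chr1\t9000\t15500\tL1PA2\t0\t-\n"
            "chr2\t50\t700\tL1PA7\t0\t+\n"
        )
        loci = read_te_annotation(path)
        assert [l.subfamily for l in loci] == ["L1HS", "L1PA2", "L1PA7"]
        assert loci[1].interval == GenomicInterval("chr1", 9000, 15500, "-")
        # ids generated from name + coordinates are unique and stable
        assert loci[0].locus_id == "L1HS_chr1_100_7000"

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t7000\tL1HS\t0\t+\nchr1\tnotanumber\t8\tx\n")
        with pytest.raises(ValueError, match="line 2"):
            read_te_annotation(path)

    def test_duplicate_locus_id_rejected(self, tmp_path):
        path = tmp_path / "dup.bed"
        path.write_text(
            "chr1\t100\t7000\tA|L1HS|L1\t0\t+\nchr2\t100\t7000\tA|L1HS|L1\t0\t+\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_te_annotation(path)

    def test_bed_round_trip_preserves_ids_and_intervals(self, tmp_path):
        rng = np.random.default_rng(1)
        loci = random_loci(rng, 20)
        path = tmp_path / "rt.bed"
        write_te_bed(loci, path)
        assert read_te_annotation(path) == loci

    def test_gtf_round_trip(self, tmp_path, small_annotation):
        loci, _, _ = small_annotation
        path = tmp_path / "rt.gtf"
        write_te_gtf(loci, path)
        assert read_te_annotation(path) == list(loci)


class TestSelectFullLengthYoung:
    def test_boundary_and_subfamily_rules(self):
        assert select_full_length_young([_locus(0, 6000)]) == []  # strict >
        assert select_full_length_young([_locus(0, 6500, subfam="L1PA7")]) == []
        kept = select_full_length_young([_locus(0, 6001)])
        assert len(kept) == 1

    def test_matches_bruteforce_filter_on_fixture(self):
        rng = np.random.default_rng(2)
        loci = []
        for i in range(10):
            start = int(rng.integers(0, 1000))
            length = int(rng.choice([3000, 6000, 6500, 8000]))
            subfam = str(rng.choice(["L1HS", "L1PA3", "L1PA7"]))
            loci.append(_locus(start, start + length, subfam=subfam, locus_id=f"L{i}"))
        expected = [
            l for l in loci
            if l.length > 6000 and l.subfamily in {"L1HS", "L1PA2", "L1PA3", "L1PA4"}
        ]
        assert select_full_length_young(loci) == expected


class TestPromoterWindow:
    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (1000, 8000, "+", (1000, 1900)),
            (1000, 8000, "-", (7100, 8000)),
            (1000, 1500, "+", (1000, 1500)),  # clipped to element length
        ],
    )
    def test_examples(self, start, end, strand, expected):
        win = promoter_window(_locus(start, end, strand))
        assert (win.interval.start, win.interval.end) == expected
        assert win.span == expected[1] - expected[0]

    def test_unstranded_locus_rejected(self):
        locus = TELocus("x", GenomicInterval("chr1", 0, 7000, "."), "L1HS")
        with pytest.raises(ValueError):
            promoter_window(locus)

    def test_window_contained_for_random_loci(self):
        rng = np.random.default_rng(3)
        for locus in random_loci(rng, 50):
            win = promoter_window(locus, span=900)
            assert win.span == min(900, locus.length)
            assert win.interval.start >= locus.interval.start
            assert win.interval.end <= locus.interval.end


class TestNearestFeatureDistance:
    def test_intragenic_overlap(self):
        res = nearest_feature_distance(_gene(1000, 2000), [_locus(1500, 9000)])
        assert (res.distance, res.bin) == (0.0, "intragenic")

    def test_inclusive_50kb_boundary(self):
        res = nearest_feature_distance(_gene(0, 1000), [_locus(51_000, 58_000)])
        assert res.distance == 50_000
        assert res.bin == "within_cutoff"

    def test_no_same_chrom_locus_is_infinite(self):
        locus = TELocus("a", GenomicInterval("chr9", 0, 7000, "+"), "L1HS")
        res = nearest_feature_distance(_gene(0, 1000), [locus])
        assert math.isinf(res.distance)
        assert res.bin == "beyond_cutoff"

    def test_empty_loci_error(self):
        with pytest.raises(ValueError):
            nearest_feature_distance(_gene(0, 1000), [])

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(4)
        genes = random_genes(rng, 20, max_pos=60_000)
        loci = random_loci(rng, 10, max_pos=60_000, max_len=8000)
        for gene in genes:
            got = nearest_feature_distance(gene, loci)
            assert tuple(got) == brute_nearest(gene, loci)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        genes = random_genes(rng, 5, max_pos=5_000)
        loci = random_loci(rng, 5, max_pos=5_000)
        shift = 10_000
        for gene in genes:
            moved_gene = GeneModel(
                gene.gene_id,
                GenomicInterval(
                    gene.interval.chrom, gene.interval.start + shift,
                    gene.interval.end + shift, gene.strand,
                ),
                tuple(
                    GenomicInterval(e.chrom, e.start + shift, e.end + shift, e.strand)
                    for e in gene.exons
                ),
            )
            moved_loci = [
                TELocus(
                    l.locus_id,
                    GenomicInterval(
                        l.interval.chrom, l.interval.start + shift,
                        l.interval.end + shift, l.interval.strand,
                    ),
                    l.subfamily,
                )
                for l in loci
            ]
            assert (
                nearest_feature_distance(gene, loci).distance
                == nearest_feature_distance(moved_gene, moved_loci).distance
            )


class TestGenomicContext:
    def test_antisense_host(self):
        locus = _locus(1200, 1800, "+")
        assert classify_genomic_context(locus, [_gene(1000, 9000, "-")]) == "intragenic_antisense"

    def test_intergenic(self):
        assert classify_genomic_context(_locus(0, 7000), [_gene(9000, 10_000)]) == "intergenic"

    def test_largest_overlap_host_wins(self):
        locus = _locus(1000, 2000, "+")
        genes = [
            _gene(1900, 5000, "-", gene_id="small_overlap"),
            _gene(0, 1800, "+", gene_id="large_overlap"),
        ]
        assert classify_genomic_context(locus, genes) == "intragenic_sense"


def test_gene_gtf_round_trip(tmp_path, small_annotation):
    _, genes, _ = small_annotation
    path = tmp_path / "genes.gtf"
    write_gene_gtf(genes, path)
    back = read_gene_annotation(path)
    assert back == list(genes)
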