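import numpy as np
import pandas as pd
import pytest

from l1ll.annotations import GeneModel, TELocus
from l1ll.intervals import GenomicInterval
from l1ll.quantify import (
    NormalizedMatrix,
    call_expressed,
    count_genes,
    count_over_features,
    log2_heatmap_transform,
    make_read_table,
    normalize_by_size_factors,
    partition_expression_across_conditions,
    read_read_table,
    read_sam,
    rpkm,
    size_factors_median_of_ratios,
    write_read_table,
)
from l1ll.simulate import CONDITION_CONTROL, simulate_reads

from conftest import random_loci
from oracles import brute_count_genes, brute_count_loci


def _read(chrom, start, end, strand, sample="s1", unique=True):
    return dict(
        chrom=chrom, start=start, end=end, strand=strand,
        sample_id=sample, unique=unique, barcode=None,
    )


def _locus(locus_id, start, end, strand):
    return TELocus(locus_id, GenomicInterval("chr1", start, end, strand), "L1HS")


class TestCountOverFeatures:
    def test_no_reads_gives_zero_matrix(self):
        m = count_over_features(make_read_table([]), [_locus("a", 0, 7000, "+")],
                                samples=["s1"])
        assert m.sense.to_numpy().sum() == 0
        assert m.antisense.to_numpy().sum() == 0

    def test_strand_rule_sense_vs_antisense(self):
        reads = make_read_table([_read("chr1", 100, 400, "+")])
        m = count_over_features(reads, [_locus("a", 0, 7000, "-")])
        assert m.antisense.loc["a", "s1"] == 1
        assert m.sense.loc["a", "s1"] == 0

    def test_non_unique_reads_skipped(self):
        reads = make_read_table([_read("chr1", 100, 400, "+", unique=False)])
        m = count_over_features(reads, [_locus("a", 0, 7000, "+")], samples=["s1"])
        assert m.sense.to_numpy().sum() == 0

    def test_matches_bruteforce_on_overlapping_loci(self):
        rng = np.random.default_rng(10)
        # deliberately overlapping loci exercise the interval-tree path
        loci = [
            _locus("a", 0, 3000, "+"),
            _locus("b", 2000, 6000, "-"),
            _locus("c", 2500, 4000, "+"),
            _locus("d", 8000, 9000, "+"),
            _locus("e", 8500, 9500, "-"),
        ]
        reads = make_read_table(
            [
                _read(
                    "chr1", s, s + int(rng.integers(50, 400)),
                    str(rng.choice(["+", "-"])),
                    sample=str(rng.choice(["s1", "s2"])),
                    unique=bool(rng.random() < 0.9),
                )
                for s in rng.integers(0, 10_000, size=200)
            ]
        )
        m = count_over_features(reads, loci, samples=["s1", "s2"])
        sense, anti = brute_count_loci(reads, loci)
        pd.testing.assert_frame_equal(m.sense, sense[["s1", "s2"]], check_dtype=False)
        pd.testing.assert_frame_equal(m.antisense, anti[["s1", "s2"]], check_dtype=False)

    def test_single_assignment_and_conservation(self, small_cfg, small_annotation):
        loci, genes, truth = small_annotation
        reads = simulate_reads(loci, genes, truth, small_cfg, CONDITION_CONTROL)
        m = count_over_features(reads, loci)
        n_unique = int(reads["unique"].sum())
        assert m.total_count() <= n_unique


class TestCountGenes:
    def _gene(self, gene_id, strand, exons):
        ivs = tuple(GenomicInterval("chr1", s, e, strand) for s, e in exons)
        span = GenomicInterval("chr1", ivs[0].start, ivs[-1].end, strand)
        return GeneModel(gene_id, span, ivs)

    def test_strand_requirement(self):
        gene = self._gene("g", "-", [(100, 500)])
        hit = make_read_table([_read("chr1", 200, 300, "-")])
        miss = make_read_table([_read("chr1", 200, 300, "+")])
        assert count_genes(hit, [gene]).sense.loc["g", "s1"] == 1
        assert count_genes(miss, [gene], samples=["s1"]).sense.loc["g", "s1"] == 0

    def test_intron_only_read_not_counted(self):
        gene = self._gene("g", "+", [(0, 100), (500, 600)])
        reads = make_read_table([_read("chr1", 200, 400, "+")])
        assert count_genes(reads, [gene], samples=["s1"]).sense.loc["g", "s1"] == 0

    def test_gene_body_mode_counts_intronic_read(self):
        gene = self._gene("g", "+", [(0, 100), (500, 600)])
        reads = make_read_table([_read("chr1", 200, 400, "+")])
        m = count_genes(reads, [gene], mode="gene_body")
        assert m.sense.loc["g", "s1"] == 1

    def test_matches_bruteforce_on_fixture(self):
        rng = np.random.default_rng(11)
        genes = [
            self._gene("g1", "+", [(0, 300), (600, 900)]),
            self._gene("g2", "-", [(800, 1200), (1500, 1800)]),
            self._gene("g3", "+", [(1700, 2500)]),
        ]
        reads = make_read_table(
            [
                _read(
                    "chr1", s, s + int(rng.integers(30, 250)),
                    str(rng.choice(["+", "-"])),
                )
                for s in rng.integers(0, 2600, size=100)
            ]
        )
        got = count_genes(reads, genes, samples=["s1"])
        expected = brute_count_genes(reads, genes)
        pd.testing.assert_frame_equal(got.sense, expected[["s1"]], check_dtype=False)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 30], "b": [5, 9, 30]})
        sf = size_factors_median_of_ratios(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_documented_three_gene_fixture(self):
        counts = pd.DataFrame({"A": [2, 4, 8], "B": [4, 8, 16]})
        sf = size_factors_median_of_ratios(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_column_scaling_moves_factor_ratio_by_c(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.integers(5, 200, size=(50, 3)), columns=["a", "b", "c"]
        )
        sf = size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 4
        sf2 = size_factors_median_of_ratios(scaled)
        assert np.isclose((sf2["b"] / sf2["a"]), 4 * (sf["b"] / sf["a"]))

    def test_no_common_positive_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_of_ratios(counts)

    def test_agrees_with_pydeseq2_reference(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.integers(1, 500, size=(100, 4)),
                              columns=list("abcd"))
        sf = size_factors_median_of_ratios(counts)
        _, ref = pydeseq2.deseq2_norm(counts.T.to_numpy())
        assert np.allclose(sf.to_numpy(), ref)


class TestNormalization:
    def test_size_factor_division(self):
        counts = pd.DataFrame({"s1": [10], "s2": [10]}, index=["f"])
        sf = pd.Series({"s1": 1.0, "s2": 2.0})
        norm = normalize_by_size_factors(counts, sf)
        assert norm.values.loc["f", "s1"] == 10.0
        assert norm.values.loc["f", "s2"] == 5.0
        assert norm.normalization == "size_factor"

    def test_missing_sample_error(self):
        counts = pd.DataFrame({"s1": [1], "s2": [1]})
        with pytest.raises(ValueError, match="s2"):
            normalize_by_size_factors(counts, pd.Series({"s1": 1.0}))

    def test_rpkm_closed_form(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["f1", "f2"])
        norm = rpkm(counts, {"f1": 1000, "f2": 2000}, {"s1": 1_000_000})
        assert norm.values.loc["f1", "s1"] == 100.0
        assert norm.values.loc["f2", "s1"] == 0.0

    def test_rpkm_rejects_zero_length_or_library(self):
        counts = pd.DataFrame({"s1": [1]}, index=["f"])
        with pytest.raises(ValueError):
            rpkm(counts, {"f": 0}, {"s1": 10})
        with pytest.raises(ValueError):
            rpkm(counts, {"f": 100}, {"s1": 0})

    def test_log2_pseudocount_values(self):
        norm = NormalizedMatrix(pd.DataFrame({"s": [0.0, 1.0, 7.0]}), "size_factor")
        out = log2_heatmap_transform(norm)
        assert out.values["s"].tolist() == [0.0, 1.0, 3.0]
        assert out.normalization == "log2p1"


class TestExpressedCalling:
    def _norm(self, data, samples):
        return NormalizedMatrix(pd.DataFrame(data, columns=samples), "size_factor")

    def test_threshold_is_strict(self):
        norm = self._norm([[1.9, 2.0]], ["s1", "s2"])
        assert call_expressed(norm, ["s1", "s2"]) == set()

    def test_single_high_sample_suffices(self):
        norm = NormalizedMatrix(
            pd.DataFrame({"s1": [0.0], "s2": [2.1]}, index=["locus"]), "size_factor"
        )
        assert call_expressed(norm, ["s1", "s2"]) == {"locus"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(14)
        norm = NormalizedMatrix(
            pd.DataFrame(rng.uniform(0, 5, size=(100, 3)), columns=["a", "b", "c"]),
            "size_factor",
        )
        low = call_expressed(norm, ["a", "b", "c"], threshold=1.0)
        high = call_expressed(norm, ["a", "b", "c"], threshold=3.0)
        assert high <= low

    def test_empty_sample_list_error(self):
        norm = self._norm([[1.0]], ["s1"])
        with pytest.raises(ValueError):
            call_expressed(norm, [])

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(15)
        idx = [f"L{i}" for i in range(100)]
        norm_b = NormalizedMatrix(
            pd.DataFrame(rng.uniform(0, 4, size=(100, 2)), index=idx,
                         columns=["o1", "o2"]),
            "size_factor",
        )
        expressed_a = set(rng.choice(idx, size=60, replace=False))
        silenced, detected = partition_expression_across_conditions(
            expressed_a, norm_b, ["o1", "o2"]
        )
        assert silenced | detected == expressed_a
        assert silenced & detected == set()

    def test_partition_empty_input(self):
        norm_b = NormalizedMatrix(pd.DataFrame({"o": [3.0]}, index=["x"]), "size_factor")
        assert partition_expression_across_conditions(set(), norm_b, ["o"]) == (set(), set())

    def test_partition_missing_feature_error(self):
        norm_b = NormalizedMatrix(pd.DataFrame({"o": [3.0]}, index=["x"]), "size_factor")
        with pytest.raises(ValueError):
            partition_expression_across_conditions({"y"}, norm_b, ["o"])


def test_read_table_round_trip(tmp_path):
    reads = make_read_table(
        [
            _read("chr1", 0, 100, "+"),
            _read("chr2", 5, 60, "-", sample="s2", unique=False),
        ]
    )
    path = tmp_path / "reads.tsv"
    write_read_table(reads, path)
    back = read_read_table(path)
    pd.testing.assert_frame_equal(
        back.drop(columns="barcode"), reads.drop(columns="barcode")
    )


def test_read_sam_fragment_strand_and_uniqueness(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:10000\n"
        "r1\t0\tchr1\t101\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNH:i:1\n"
        "r2\t16\tchr1\t201\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNH:i:1\n"
        "r3\t0\tchr1\t301\t0\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNH:i:4\n"
    )
    reads = read_sam(sam, sample_id="s1", mate_flip=True)
    assert len(reads) == 3
    # dUTP correction: a forward-aligned read comes from a minus-strand fragment
    assert reads.loc[0, "strand"] == "-"
    assert reads.loc[1, "strand"] == "+"
    assert reads.loc[0, "start"] == 100
    assert bool(reads.loc[2, "unique"]) is False
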