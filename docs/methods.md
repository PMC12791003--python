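# Methods

## Coordinates and interval conventions

All internal coordinates are 0-based, half-open (BED convention). GTF
readers/writers convert to and from 1-based closed coordinates. Two
intervals overlap when they share at least one base; abutting half-open
intervals do not overlap. Interval intersection uses an interval tree;
the counting kernel additionally has a vectorised binary-search fast path
that activates when the per-chromosome feature intervals are disjoint
(true for curated TE annotations and the synthetic genome) and falls back
to the tree for overlapping feature sets. Both paths implement the same
assignment rule and are compared against an exhaustive pairwise oracle in
the test suite.

## Locus selection and promoter windows

A locus is *full-length young* when its span is strictly greater than
6,000 bp and its subfamily is one of L1HS, L1PA2, L1PA3, L1PA4 — the
lineages that retain an intact 5'UTR promoter. The promoter window is the
first 900 bp from the element's 5' end in element orientation (plus
strand: `[start, start+900)`; minus strand: `[end−900, end)`), clipped to
the element for shorter inputs. Orientation is mandatory here and for
genomic-context classification; unstranded records are rejected.

## Read counting

Fragments (read pairs collapsed to one record) are counted only when
uniquely mapped (`NH == 1`, or `MAPQ ≥ 255` when the tag is absent; the
TSV read-table dialect carries an explicit boolean). Each fragment
increments exactly one feature: the one with the largest overlap, ties
resolved towards the smaller feature start and then the lexicographically
smaller id. TE counts are split into sense and antisense blocks by
comparing the fragment's transcription strand with the element strand;
the SAM reader applies the dUTP-protocol mate flip (reversely stranded
libraries) controlled by a flag. Gene counting uses the merged exon union
(gene-body mode available) and by default requires strand agreement,
matching a reversely-stranded featureCounts run. Multi-overlap is rare in
practice with unique mapping and a non-overlapping curated TE annotation,
but the rule is required for arbitrary inputs and for the oracle tests.

## Normalization and the expressed-locus rule

Size factors are the median-of-ratios statistic computed from gene
counts: for genes with strictly positive counts in every sample, the
sample factor is the median of `count / geometric mean`. No rescaling is
applied afterwards, and TE counts are divided by the gene-derived factors
(TE counts themselves never enter the factor estimation, so a global
shift in TE expression between conditions is not normalized away). When
no gene is positive in all samples the function raises rather than
silently switching to a pseudo-reference. A locus is *expressed* in a
condition when at least one of that condition's samples has a normalized
count strictly above 2; the threshold and the strictness are exposed as
arguments. Size factors are computed once across all samples of an
experiment; the expressed call then restricts to the condition's columns.
The call uses the sense block only by default — whether antisense
transcription should count toward "expressed" is genuinely ambiguous, so
the caller can pass any matrix. RPKM uses total uniquely mapped reads as
the library size. The partition of condition-A-expressed loci into
silenced/detected in condition B is, by construction, disjoint and
exhaustive; the test suite asserts this as a property.

## Peak integration and dCas9 classification

Peaks carry caller-reported p-values and are filtered at p < 0.05
(strict) before any intersection; no re-computation of significance is
attempted. A promoter is H3K4me3-marked when at least one significant
peak overlaps its window by ≥1 bp. For the CRISPRi dCas9 analysis,
treatment peaks are expanded by 100 bp on both sides, peaks overlapping
any control (non-targeting gRNA) peak are discarded — crosslinked dCas9
CUT&RUN produces technical peaks present in both conditions, and these
must not be read as off-target binding — and the survivors are split by
overlap with full-length young L1 bodies into on-target and off-target
binding sites. The number of control-shared dropped peaks is reported on
the result object. The control set is left unexpanded by default (the
flanking step precedes the control filter); a flag expands both.

## Promoter methylation

Per-read binary CpG calls are pooled at the call level over the promoter
window: percent methylation = 100 × methylated calls / total calls,
pooling across reads and CpG sites. A per-site averaging mode (mean of
per-site fractions) is available. Loci/samples with fewer than
`min_calls = 5` supporting calls are reported as undefined rather than
0% or 100% — a single read should not produce an extreme value. The
methylation–expression relation is summarized per subfamily by OLS of
percent methylation on size-factor-normalized expression, with the
two-sided slope p-value from the t distribution (n−2 df); groups with
fewer than 3 usable loci are skipped with a warning, and a constant
response is reported as slope 0, R² 0 rather than NaN.

## Cis regulation

DE tables are consumed, not computed: fold-change and adjusted-p
estimation belong to the upstream DE tool. Classification uses
p_adj < 0.05 and |log₂FC| ≥ 1 with the boundary included (the threshold
is magnitude-style); undefined p_adj is not significant. Distance binning
measures the edge-to-edge gap between the gene body and the locus body —
TSS anchoring is not used because the choice is not forced by the
analysis; a gap of exactly 50,000 bp falls in the ≤50 kb bin, and a
zero-length gap (adjacent intervals) is binned as ≤50 kb, not intragenic.
The consistency rule takes a designated base comparison: consistent up
requires base log₂FC > 0.25 and positive log₂FC in every other
comparison (down mirrored); genes missing a fold change anywhere are
excluded rather than imputed. The exon-usage split partitions exons
upstream/downstream of an intronic L1 in transcript orientation (an exon
overlapping the planted position counts as downstream, since the element
transcribes into it) and flags the L1-promoter pattern when downstream
exons dominate the control, drop under CRISPRi, and upstream means stay
within a 1.5× fold tolerance — compared exactly, so the flag is invariant
under uniform count rescaling.

## Pseudo-bulk

Cell QC is single-pass per sample: mean and SD of the detected-feature
count are computed once on the pre-filter population; cells with
mitochondrial content strictly over 10% or feature counts strictly
outside `[mean − 1·SD, mean + 2·SD]` are removed (boundaries kept).
Barcodes are keyed by (sample, barcode), so the same barcode sequenced in
two samples is two cells. Reads without a kept, assigned barcode are
discarded and counted. Each cluster's pooled reads are then quantified
exactly like a bulk sample; size factors are computed across
pseudoclusters from the gene count matrix and divide the pseudobulked TE
counts. A cluster with no gene counts has no defined factor and raises,
naming the cluster. Because already-aligned unique reads are partitioned
(rather than re-aligned per cluster), per-cluster count matrices sum
exactly to the whole-sample matrix — asserted as a conservation test.

## Growth comparison

Areas are compared per (batch, day) with the classical pooled-variance
two-sample Student's t-test, two-sided, oriented control minus treatment;
Welch's correction is a flag. No multiple-testing correction is applied
across timepoints. Timepoints with fewer than two measurements in either
condition yield an undefined statistic with a warning, and the test can
be restricted to selected days.

## Synthetic data generator

The generator emulates the *structure* of the study's data at desk scale,
deterministically per seed (each component draws from its own seeded
substream, so regenerating one file type does not perturb the others).

- **Genome and annotation.** Two 5 Mb chromosomes by default; features
  are placed in non-overlapping slots: 200 L1 loci (half full-length
  young at 6,001–7,500 bp; half decoys — short young or long old
  subfamilies), and 300 genes with 2–5 exons. Fifty *cis genes* each host
  one full-length young L1 in antisense orientation inside the intron
  between two lowly-expressed canonical upstream exons and three
  highly-expressed L1-driven downstream exons, mirroring chimeric
  antisense-promoter transcripts; cis-gene biotypes are drawn 2:1
  lncRNA:protein-coding. Sixty percent of full-length young loci are
  planted as expressed (all cis drivers among them); targeted = expressed.
- **Counts.** Per-feature fragment counts are negative-binomial
  (dispersion 0.1; variance m + 0.1 m²) with mean proportional to the
  planted expression weight, a ±20% per-sample depth factor and 50,000
  fragments per sample; CRISPRi multiplies targeted-locus and cis-gene
  downstream-exon means by (1 − silencing efficiency), default 0.9.
  Fragments (300 bp) are placed uniformly within features on the
  transcribed strand; 5% multi-mapping decoy fragments are emitted with
  `unique = False`. The 3'-end positional bias of real L1 RNA-seq
  coverage is deliberately not modeled.
- **Methylation.** CpG sites every 50 bp in each promoter; ~10 reads per
  promoter and sample (two samples); per-read methylation probability is
  beta-binomial (concentration 20) around the planted level — 10% for
  expressed loci, 85% for silent, ±5 points of per-locus jitter (exact at
  the 0/100 limits so fully (un)methylated configurations stay exact).
- **Peaks.** One significant H3K4me3 peak per expressed-locus promoter
  plus background peaks away from young L1s; dCas9 treatment peaks at the
  first 200 bp of every targeted locus plus 30 shared technical peaks
  present identically in treatment and control, placed ≥300 bp clear of
  any locus so the flank-expanded control filter removes exactly them.
- **DE tables, growth, QC.** Cis genes carry their planted log₂FC
  (log₂(1 − efficiency) ≈ −3.3) plus N(0, 0.2) noise and significant
  adjusted p; other genes draw from a null. A standalone helper plants an
  exact down/up/null table (e.g. 99 down / 6 up in 1,000 genes) for
  threshold-recovery tests. Organoid areas grow 1.2×/day in both
  conditions until day 10, after which treatment slows to 1.1×/day, with
  10% log-normal noise, n = 20 per condition, measured on days 2–15. QC
  metrics place a tight core population (1,900–2,100 features, <5%
  mitochondrial) plus planted outliers far outside the single-pass
  bounds, so exact outlier recovery is guaranteed by construction.
- **Single-cell mode.** The bulk fragment model is reused per cluster
  (4 clusters × 50 barcodes, 20,000 fragments total) with one planted
  cluster-private locus expressed only in cluster 2; no UMI model.

What passing recovery tests shows — and what it does not: the pipeline
correctly implements its rules and recovers planted structure under
NB/beta-binomial noise at realistic depths. It does not demonstrate
robustness to mappability artifacts, positional coverage bias, doublets,
ambient RNA, or mis-annotation, none of which the generator emulates.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run 100 random instances (≈40×40 interval sets,
120–150 reads over 6–8 features). Parameter recovery sweeps 100 generator
seeds at the default scale above; the growth check likewise uses 100
seeds. Worked examples reuse the study's printed scale (2,323 loci
partitioned into 750 + 1,573; 39,181 + 27,025 = 66,206 nuclei), with the
partition realized on constructed normalized matrices and verified
through the same calling/partition code paths as real data.

## Known limitations

- No multimapper rescue: subfamily-level EM reassignment is out of scope,
  so quantification reflects uniquely mappable loci only.
- DE estimation, peak calling, clustering and alignment are consumed as
  inputs, never recomputed.
- The expressed-locus threshold (normalized count > 2) is a convention,
  not an estimated detection limit; its boundary behaviour is strict and
  documented.
- Distance binning uses gene bodies; a TSS-anchored variant would shift
  genes near the boundary between bins.
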