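# l1ll — locus-level LINE-1 expression, epigenome and CRISPRi analysis

Most of the ~500,000 LINE-1 (L1) copies in the human genome are
degenerate, but the evolutionarily young subfamilies — human-specific
L1HS and hominoid-specific L1PA2–L1PA4 — retain full-length (>6 kb)
copies with an intact bidirectional promoter in their 5'UTR. In
pluripotent stem cells many of these individual loci are transcribed,
their promoters carry the active H3K4me3 mark and low CpG methylation,
and their antisense promoter can drive chimeric transcripts of flanking
genes. `l1ll` implements the locus-resolution analysis of this biology as
a reusable, tested pipeline:

- **Annotations** — parse RepeatMasker-style TE GTF/BED and gene GTF,
  select full-length young loci (length > 6 kb, strictly; subfamily in
  {L1HS, L1PA2, L1PA3, L1PA4}), derive promoter windows (first 900 bp in
  element orientation), gene–locus distances and genomic-context labels.
- **Quantification** — stranded counting of uniquely mapped fragments
  over loci (sense/antisense) and genes (exon union, reverse-stranded
  protocol); median-of-ratios size factors
  `s_j = median_g ( k_gj / (∏_j k_gj)^{1/n} )` computed from gene counts;
  RPKM (`10⁹·k / (L·N)`); log₂(x+1); the expressed-locus rule — a locus is
  *expressed* in a condition when at least one sample's size-factor
  normalized count exceeds 2 — and the cross-condition expressed →
  silenced/detected partition.
- **Epigenome** — H3K4me3 peak × promoter intersection (significant peaks
  at caller p < 0.05), and dCas9 CUT&RUN on-/off-target classification for
  CRISPRi experiments: flank peaks by 100 bp, drop anything shared with
  the non-targeting control (technical artifacts of crosslinked dCas9
  CUT&RUN), intersect survivors with full-length young L1 bodies.
- **Methylation** — pool per-read CpG calls over promoter windows into a
  percent-methylated value per locus and sample, summarize by subfamily,
  and regress promoter methylation on normalized expression (OLS per
  subfamily; active loci are hypomethylated, so slopes are negative).
- **Cis regulation** — classify DE tables (p_adj < 0.05, |log₂FC| ≥ 1),
  bin downregulated genes by distance to the nearest (silenced) L1
  (intragenic / ≤50 kb / >50 kb), apply the cross-guide consistency rule
  (base |log₂FC| > 0.25 and same sign in every other comparison), and
  split exon usage around an intronic antisense L1 to flag L1-driven
  alternative isoforms.
- **Pseudo-bulk** — per-sample cell QC (mitochondrial % > 10 removed;
  detected features outside mean −1 SD … mean +2 SD removed), barcode →
  cluster read backtracking, per-cluster TE/gene counting with
  per-pseudocluster size factors.
- **Phenotype** — organoid growth curves compared per batch and day with
  a pooled-variance Student's t-test.
- **Synthetic data** — a fully seeded generator that plants ground truth
  for every stage (expressed vs silent hypomethylated/methylated loci,
  cis genes driven by intronic antisense L1s, negative-binomial counts
  with CRISPRi silencing, beta-binomial CpG calls, peak sets with a
  shared-artifact class, clustered barcoded reads, diverging growth
  curves), used by the recovery test suite.

## Worked example

```python
import pandas as pd
from l1ll import *
from l1ll.simulate import (simulate_annotation, simulate_reads, simulate_peaks,
                           CONDITION_CONTROL, CONDITION_CRISPRI)
from l1ll.epigenome import significant_peaks

cfg = SimulationConfig(seed=7)
loci, genes, truth = simulate_annotation(cfg)
fl = select_full_length_young(loci)          # 100 of 200 loci
reads = pd.concat([simulate_reads(loci, genes, truth, cfg, c)
                   for c in (CONDITION_CONTROL, CONDITION_CRISPRI)])
samples = [f"{c}_rep{i+1}" for c in ("control", "crispri") for i in range(3)]
te  = count_over_features(reads, fl, samples=samples)
gn  = count_genes(reads, genes, samples=samples)
sf  = size_factors_median_of_ratios(gn.sense)
norm = normalize_by_size_factors(te.sense, sf)
expressed = call_expressed(norm, ["control_rep1", "control_rep2", "control_rep3"])
print(len(expressed), len(truth.expressed_loci))

peaks = simulate_peaks(loci, truth, cfg)
cls = classify_dcas9_peaks(significant_peaks(peaks["dcas9_treatment"]),
                           significant_peaks(peaks["dcas9_control"]), fl)
print(len(cls.on_target), len(cls.off_target), cls.n_control_dropped)
```

prints

```
60 60
60 0 30
```

All 60 planted expressed loci are recovered by the normalized-count > 2
rule (no false positives among the 40 silent full-length loci), and the
dCas9 classifier identifies all 60 targeted promoters as on-target while
discarding the 30 planted technical peaks shared with the control — the
artifact class that would otherwise masquerade as off-target binding.
The same dataset yields negative methylation–expression slopes in every
subfamily (e.g. L1HS: slope −0.79, R² = 0.71) and a day-15 organoid size
difference of 155,953 vs 97,481 µm² (t = 13.49, p = 4.6e-16).

A command-line interface mirrors the main steps:

```bash
l1ll simulate --seed 7 --out data/
l1ll quantify --te data/te.gtf --genes data/genes.gtf \
              --reads data/reads_bulk.tsv --out-prefix quant
l1ll dcas9-classify --treatment data/peaks_dcas9_treatment.bed \
                    --control data/peaks_dcas9_control.bed \
                    --loci data/te.gtf --out-prefix dcas9
l1ll growth --areas data/areas.tsv --out growth.tsv
```

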