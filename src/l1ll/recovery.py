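"""End-to-end parameter recovery on synthetic data.

Runs the full pipeline on one generated dataset and scores it against the
planted ground truth: expressed-locus calling (sensitivity / FDR), dCas9
on-target classification, the sign of the methylation-expression
regression slope, and cis-gene assignment. Shared by the test suite and
the acceptance script so both measure the same computation.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .annotations import promoter_window, select_full_length_young
from .cis import cis_assignment, classify_de
from .epigenome import classify_dcas9_peaks, significant_peaks
from .methylation import (
    aggregate_promoter_methylation,
    methylation_expression_regression,
)
from .quantify import (
    call_expressed,
    count_genes,
    count_over_features,
    normalize_by_size_factors,
    size_factors_median_of_ratios,
)
from .simulate import (
    CONDITION_CONTROL,
    CONDITION_CRISPRI,
    SimulationConfig,
    simulate_annotation,
    simulate_de_tables,
    simulate_methylation,
    simulate_peaks,
    simulate_reads,
)


def run_parameter_recovery(cfg: SimulationConfig) -> dict:
    """One full generate-analyze-score cycle; returns the recovery metrics."""
    loci, genes, truth = simulate_annotation(cfg)
    fl_young = select_full_length_young(loci)

    # --- expressed-locus calling -------------------------------------------
    reads = pd.concat(
        [
            simulate_reads(loci, genes, truth, cfg, CONDITION_CONTROL),
            simulate_reads(loci, genes, truth, cfg, CONDITION_CRISPRI),
        ],
        ignore_index=True,
    )
    control_samples = [
        f"{CONDITION_CONTROL}_rep{i + 1}" for i in range(cfg.n_samples_per_condition)
    ]
    all_samples = control_samples + [
        f"{CONDITION_CRISPRI}_rep{i + 1}" for i in range(cfg.n_samples_per_condition)
    ]
    te_counts = count_over_features(reads, fl_young, samples=all_samples)
    gene_counts = count_genes(reads, genes, samples=all_samples)
    sf = size_factors_median_of_ratios(gene_counts.sense)
    norm = normalize_by_size_factors(te_counts.sense, sf)
    called = call_expressed(norm, control_samples)
    truth_expressed = truth.expressed_loci
    truth_silent = {l.locus_id for l in fl_young} - truth_expressed
    tp = len(called & truth_expressed)
    fp = len(called & truth_silent)
    fn = len(truth_expressed - called)
    sensitivity = tp / max(tp + fn, 1)
    fdr = fp / max(tp + fp, 1)

    # --- dCas9 on-/off-target classification --------------------------------
    peaks = simulate_peaks(loci, truth, cfg)
    cls = classify_dcas9_peaks(
        significant_peaks(peaks["dcas9_treatment"]),
        significant_peaks(peaks["dcas9_control"]),
        fl_young,
    )
    on_loci = set()
    for peak in cls.on_target:
        for locus in fl_young:
            if (
                locus.interval.chrom == peak.interval.chrom
                and min(locus.interval.end, peak.interval.end + 100)
                > max(locus.interval.start, peak.interval.start - 100)
            ):
                on_loci.add(locus.locus_id)
    dcas9_recall = len(on_loci & truth.targeted_loci) / max(len(truth.targeted_loci), 1)
    dcas9_false_on = len(on_loci - truth.targeted_loci)

    # --- methylation-expression regression ----------------------------------
    calls = simulate_methylation(loci, truth, cfg)
    proms = [promoter_window(l) for l in fl_young]
    meth = aggregate_promoter_methylation(calls, proms)
    meth_per_locus = meth.groupby("locus_id")["percent"].mean()
    expr_per_locus = norm.values[control_samples].mean(axis=1)
    fit = methylation_expression_regression(
        meth_per_locus,
        expr_per_locus,
        {l.locus_id: "L1_young" for l in fl_young},
    )
    slope = float(fit.loc[fit["group"] == "L1_young", "slope"].iloc[0])

    # --- cis-gene recovery ---------------------------------------------------
    de = simulate_de_tables(genes, truth, cfg)
    base = de[cfg.de_comparisons[0]]
    down = classify_de(base).down
    silenced_loci = [l for l in fl_young if l.locus_id in truth.targeted_loci]
    assignment = cis_assignment(down, genes, silenced_loci)
    near = assignment[assignment["bin"].isin(["intragenic", "within_cutoff"])]
    planted = set(truth.cis_genes)
    cis_recovered = len(set(near["gene_id"]) & planted) / max(len(planted), 1)

    return {
        "expressed_sensitivity": sensitivity,
        "expressed_fdr": fdr,
        "n_expressed_truth": len(truth_expressed),
        "n_called": len(called),
        "dcas9_recall": dcas9_recall,
        "dcas9_false_on_targets": dcas9_false_on,
        "n_control_shared_dropped": cls.n_control_dropped,
        "meth_expr_slope": slope,
        "cis_recovery": cis_recovered,
        "n_cis_genes": len(planted),
    }


def sweep_parameter_recovery(
    base_cfg: SimulationConfig, n_seeds: int, seed0: int = 0
) -> pd.DataFrame:
    """Recovery metrics over ``n_seeds`` independent generator seeds."""
    rows = []
    for i in range(n_seeds):
        seed = (seed0 * 100_003 + i) % (2**31)
        cfg = replace(base_cfg, seed=seed)
        rows.append({"seed": seed, **run_parameter_recovery(cfg)})
    return pd.DataFrame(rows)
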