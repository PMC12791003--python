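"""Promoter CpG methylation from read-level calls.

Long-read sequencing yields a binary 5mCG call per read per CpG site.
Promoter methylation of a locus is the percentage of methylated calls
among all calls falling inside its promoter window (call-level pooling
across reads and sites; a per-site averaging mode is available). Loci with
too few calls are reported as undefined rather than 0 or 100%.

The methylation-expression relationship is summarized per L1 subfamily by
ordinary least squares of promoter methylation (%) on size-factor
normalized expression; active loci are expected to be hypomethylated, so
the fitted slope is negative.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import PromoterWindow

#: Accepted spellings of the binary state column.
_STATE_MAP = {
    "methylated": 1, "m": 1, "1": 1,
    "unmethylated": 0, "u": 0, "0": 0,
}

CALL_COLUMNS = ["chrom", "pos", "read_id", "state", "sample_id"]


def read_cpg_calls(path: str | Path) -> pd.DataFrame:
    """Read per-read CpG calls from the documented TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "read_id": str, "sample_id": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: CpG call table missing columns {missing}")
    states = df["state"].astype(str).str.lower().map(_STATE_MAP)
    if states.isna().any():
        bad = df.loc[states.isna(), "state"].iloc[0]
        raise ValueError(f"{path}: unrecognized methylation state {bad!r}")
    df = df.copy()
    df["state"] = states.astype(int)
    return df[CALL_COLUMNS]


def write_cpg_calls(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["state"] = out["state"].map({1: "methylated", 0: "unmethylated"})
    out.to_csv(path, sep="\t", index=False)


def aggregate_promoter_methylation(
    calls: pd.DataFrame,
    promoters: Sequence[PromoterWindow],
    min_calls: int = 5,
    per_site: bool = False,
) -> pd.DataFrame:
    """Pool CpG calls over promoter windows per locus and sample.

    Returns a table with columns ``locus_id, sample_id, n_calls,
    n_methylated, percent``; ``percent`` is NaN when fewer than
    ``min_calls`` calls support the locus/sample. ``per_site`` averages
    per-site methylation fractions instead of pooling calls directly.
    """
    state = calls["state"]
    if not state.isin((0, 1)).all():
        raise ValueError("state column must be binary 0/1 (use read_cpg_calls)")
    rows = []
    samples = list(pd.unique(calls["sample_id"]))
    by_chrom = {chrom: grp.sort_values("pos") for chrom, grp in calls.groupby("chrom")}
    for prom in promoters:
        iv = prom.interval
        grp = by_chrom.get(iv.chrom)
        if grp is None:
            sub = calls.iloc[0:0]
        else:
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            sub = grp.iloc[lo:hi]
        for sample in samples:
            ssub = sub[sub["sample_id"] == sample]
            n_calls = len(ssub)
            n_meth = int(ssub["state"].sum())
            if n_calls >= min_calls:
                if per_site:
                    site_frac = ssub.groupby("pos")["state"].mean()
                    percent = 100.0 * float(site_frac.mean())
                else:
                    percent = 100.0 * n_meth / n_calls
            else:
                percent = np.nan
            rows.append((prom.locus_id, sample, n_calls, n_meth, percent))
    return pd.DataFrame(
        rows, columns=["locus_id", "sample_id", "n_calls", "n_methylated", "percent"]
    )


def methylation_by_group(
    meth: pd.DataFrame, group_of_locus: Mapping[str, str]
) -> pd.DataFrame:
    """Median / quartile / mean promoter methylation per group and sample.

    Loci with undefined percent are ignored; empty groups are omitted.
    """
    df = meth.dropna(subset=["percent"]).copy()
    df["group"] = df["locus_id"].map(dict(group_of_locus))
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "locus_id"].iloc[0]
        raise KeyError(f"no group defined for locus {missing!r}")
    out = (
        df.groupby(["group", "sample_id"])["percent"]
        .agg(
            n="count",
            mean="mean",
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
    )
    return out


def methylation_expression_regression(
    meth_percent: Mapping[str, float] | pd.Series,
    expression: Mapping[str, float] | pd.Series,
    group_of_locus: Mapping[str, str],
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-group OLS of promoter methylation (%) on normalized expression.

    Returns a table with slope, intercept, R^2 and the two-sided p-value of
    the slope (t distribution, n-2 df). Groups with fewer than
    ``min_points`` usable loci are skipped with a warning.
    """
    meth = pd.Series(dict(meth_percent) if not isinstance(meth_percent, pd.Series) else meth_percent)
    expr = pd.Series(dict(expression) if not isinstance(expression, pd.Series) else expression)
    common = meth.dropna().index.intersection(expr.dropna().index)
    groups = pd.Series({l: group_of_locus[l] for l in common if l in group_of_locus})
    rows = []
    for group in sorted(groups.unique()):
        loci = groups.index[groups == group]
        x = expr[loci].to_numpy(dtype=float)
        y = meth[loci].to_numpy(dtype=float)
        if len(loci) < min_points:
            warnings.warn(f"group {group!r}: only {len(loci)} points, skipping regression")
            continue
        if np.allclose(x, x[0]):
            warnings.warn(f"group {group!r}: constant predictor, skipping regression")
            continue
        if np.allclose(y, y[0]):
            # constant response: zero slope, no variance explained
            rows.append((group, len(loci), 0.0, float(y[0]), 0.0, 1.0))
            continue
        fit = stats.linregress(x, y)
        rows.append(
            (group, len(loci), fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue)
        )
    return pd.DataFrame(
        rows, columns=["group", "n", "slope", "intercept", "r_squared", "p_value"]
    )
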