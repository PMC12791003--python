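"""Organoid growth-curve comparison.

Cerebral-organoid cross-sectional areas (um^2) are measured per organoid
over differentiation days; control and treatment (L1-CRISPRi) conditions
are compared at each timepoint with a classical two-sample Student's
t-test (pooled variance, two-sided), per batch. Welch's correction is
available by flag; no multiple-testing correction is applied across
timepoints.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

AREA_COLUMNS = ["organoid_id", "condition", "batch", "day", "area"]
CONDITIONS = ("control", "treatment")


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"organoid_id": str, "condition": str, "batch": str})
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: area table missing columns {missing}")
    if (df["area"] <= 0).any():
        raise ValueError(f"{path}: areas must be positive")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"{path}: unknown condition labels {sorted(bad)}")
    return df[AREA_COLUMNS]


def write_area_table(df: pd.DataFrame, path: str | Path) -> None:
    df[AREA_COLUMNS].to_csv(path, sep="\t", index=False)


def growth_curve_test(
    measurements: pd.DataFrame,
    welch: bool = False,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Two-sample t-test of control vs treatment areas per (batch, day).

    The t statistic is oriented control minus treatment. Rows are ordered
    by batch then day; (batch, day) cells with fewer than two measurements
    in either condition get an undefined statistic and a warning. Pass
    ``days`` to restrict the comparison to selected timepoints.
    """
    df = measurements
    if days is not None:
        df = df[df["day"].isin(days)]
    rows = []
    for (batch, day), grp in df.groupby(["batch", "day"], sort=True):
        ctrl = grp.loc[grp["condition"] == "control", "area"].to_numpy(dtype=float)
        trt = grp.loc[grp["condition"] == "treatment", "area"].to_numpy(dtype=float)
        if len(ctrl) < 2 or len(trt) < 2:
            warnings.warn(
                f"batch {batch!r} day {day}: fewer than 2 measurements per condition"
            )
            t_stat, p_value = np.nan, np.nan
        else:
            res = stats.ttest_ind(ctrl, trt, equal_var=not welch)
            t_stat, p_value = float(res.statistic), float(res.pvalue)
        rows.append(
            (
                batch,
                int(day),
                len(ctrl),
                len(trt),
                float(ctrl.mean()) if len(ctrl) else np.nan,
                float(trt.mean()) if len(trt) else np.nan,
                t_stat,
                p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "batch",
            "day",
            "n_control",
            "n_treatment",
            "mean_control",
            "mean_treatment",
            "t",
            "p_value",
        ],
    )
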