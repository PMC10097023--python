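"""Relative expression of target genera from qPCR Ct values (2^-ddCt).

Each sample provides a target-genus Ct and a reference Ct (total bacteria).
dCt = Ct_target - Ct_reference removes loading differences; ddCt subtracts
the control group's mean dCt per target, so the control group's fold changes
have geometric mean exactly 1; fold = 2^-ddCt assumes doubling-per-cycle
efficiency (an efficiency-corrected E^-ddCt mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample", "group", "target", "ct_target", "ct_reference")


def _validate(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    bad_ref = ct[~np.isfinite(ct["ct_reference"].astype(float))]
    if len(bad_ref):
        raise ValueError(
            f"missing reference Ct for sample(s): {bad_ref['sample'].tolist()[:5]}"
        )
    bad_t = ct[~np.isfinite(ct["ct_target"].astype(float))]
    if len(bad_t):
        raise ValueError(
            f"missing target Ct for sample(s): {bad_t['sample'].tolist()[:5]}"
        )
    import warnings

    cts = ct[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if ((cts < 5) | (cts > 40)).any():
        warnings.warn("Ct values outside the typical 5-40 cycle range")
    return ct


def relative_expression(ct: pd.DataFrame, control_group: str,
                        efficiency: float = 2.0,
                        center: str = "mean") -> pd.DataFrame:
    """Per-(sample, target) fold change relative to the control group.

    ``center`` chooses how the control dCt baseline is located (arithmetic
    'mean' is the standard convention; 'median' is robust to outliers).
    """
    ct = _validate(ct.copy())
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct["d_ct"] = ct["ct_target"].astype(float) - ct["ct_reference"].astype(float)
    out = []
    for target, sub in ct.groupby("target", sort=False):
        control = sub[sub["group"] == control_group]
        if control.empty:
            raise ValueError(
                f"control group {control_group!r} empty for target {target!r}"
            )
        if center == "mean":
            baseline = control["d_ct"].mean()
        elif center == "median":
            baseline = control["d_ct"].median()
        else:
            raise ValueError(f"unknown center {center!r}")
        sub = sub.copy()
        sub["dd_ct"] = sub["d_ct"] - baseline
        sub["fold"] = efficiency ** (-sub["dd_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def expression_summary(folds: pd.DataFrame, control_group: str,
                       test: str = "ttest") -> pd.DataFrame:
    """Group x target summary: mean, sd, percent change vs control, p-value.

    percent change = 100 * (mean_group - mean_control) / mean_control; the
    p-value compares each group against the control with a standard
    two-sample test (Welch's t by default, rank-sum optionally).
    """
    rows = []
    for target, sub in folds.groupby("target", sort=False):
        control = sub[sub["group"] == control_group]["fold"]
        if control.empty:
            raise ValueError(f"control group missing for target {target!r}")
        c_mean = control.mean()
        for group, gsub in sub.groupby("group", sort=False):
            vals = gsub["fold"]
            if group == control_group or len(vals) < 2 or len(control) < 2:
                p = np.nan
            elif test == "ttest":
                p = float(stats.ttest_ind(vals, control, equal_var=False).pvalue)
            elif test == "wilcoxon":
                p = float(stats.ranksums(vals, control).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {
                    "target": target,
                    "group": group,
                    "mean_fold": float(vals.mean()),
                    "sd_fold": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "pct_change_vs_control": float(
                        100.0 * (vals.mean() - c_mean) / c_mean
                    ),
                    "p_vs_control": p,
                }
            )
    return pd.DataFrame(rows)
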