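"""Group comparisons: t-tests and transit-vs-stalling linear fits.

The experimental design compares a control group against an LPS-treated
(systemic inflammation) group with two-sample t-tests, pre/post tracer
injection with paired t-tests, and relates the arteriovenous mean transit
time to capillary stalling metrics by ordinary least squares across animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FitResult",
    "two_sample_ttest",
    "paired_ttest",
    "linear_fit",
    "correlate_stalls_vs_mtt",
    "GROUP_TABLE_COLUMNS",
]

#: expected columns of a cohort table (one row per animal per phase)
GROUP_TABLE_COLUMNS = (
    "animal_id",
    "group",
    "sex",
    "stall_proportion",
    "mean_stall_duration_frames",
    "mtt_s",
    "bfi_artery",
    "bfi_vein",
    "phase",
)


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def two_sample_ttest(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with distinct means: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def paired_ttest(pre, post) -> tuple[float, float]:
    """Paired t-test (one-sample t on the post - pre differences)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    if pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = post - pre
    if np.var(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t, p = sps.ttest_rel(pre, post)
    # scipy computes pre - post; report the post - pre convention
    return float(-t), float(p)


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares y ~ x with R^2 and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = sps.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def correlate_stalls_vs_mtt(table: pd.DataFrame, duration_in_seconds: bool = False) -> tuple[FitResult, FitResult]:
    """Fit MTT against stall proportion and against mean stall duration.

    Returns (fit for mtt_s ~ stall_proportion, fit for mtt_s ~ duration);
    duration is in frames unless ``duration_in_seconds``.
    """
    needed = ["stall_proportion", "mean_stall_duration_frames", "mtt_s"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns: {', '.join(missing)}")
    rows = table.dropna(subset=needed)
    if len(rows) < 3:
        raise ValueError("need >= 3 complete rows")
    duration = rows["mean_stall_duration_frames"].to_numpy()
    if duration_in_seconds:
        if "frame_interval_s" not in rows.columns:
            raise ValueError("group table missing columns: frame_interval_s")
        duration = duration * rows["frame_interval_s"].to_numpy()
    fit_prop = linear_fit(rows["stall_proportion"].to_numpy(), rows["mtt_s"].to_numpy())
    fit_dur = linear_fit(duration, rows["mtt_s"].to_numpy())
    return fit_prop, fit_dur
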