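"""Quantitative evaluation: relative error maps, ROI summaries, age trends."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RelativeErrorResult",
    "RoiSummary",
    "TrendResult",
    "relative_error",
    "roi_summary",
    "ga_trend",
    "long_format_table",
]


@dataclass
class RelativeErrorResult:
    """Voxelwise (est - true)/true over the mask plus its summary."""

    error_map: np.ndarray
    mean_abs_error: float
    n_voxels: int
    n_excluded: int  # zero-truth voxels dropped from the summary


def relative_error(
    p_est: np.ndarray, p_true: np.ndarray, mask: np.ndarray
) -> RelativeErrorResult:
    """Relative reconstruction error of a parameter map against ground truth.

    Voxels where the truth is exactly zero are excluded from the summary and
    counted. The error map is zero outside the mask and at excluded voxels.
    """
    p_est = np.asarray(p_est, float)
    p_true = np.asarray(p_true, float)
    mask = np.asarray(mask, dtype=bool)
    valid = mask & (p_true != 0)
    err = np.zeros(mask.shape, dtype=float)
    err[valid] = (p_est[valid] - p_true[valid]) / p_true[valid]
    n_excluded = int(mask.sum() - valid.sum())
    if not valid.any():
        raise ValueError("no valid (nonzero-truth) voxels in the mask")
    return RelativeErrorResult(
        error_map=err,
        mean_abs_error=float(np.mean(np.abs(err[valid]))),
        n_voxels=int(valid.sum()),
        n_excluded=n_excluded,
    )


@dataclass
class RoiSummary:
    median: float
    p25: float
    p75: float
    mean: float
    sd: float
    n: int


def roi_summary(values: np.ndarray, mask: np.ndarray | None = None) -> RoiSummary:
    """Order statistics of a map over a mask (linear-interpolation percentiles)."""
    values = np.asarray(values, float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        values = values[mask]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("no values to summarize")
    p25, med, p75 = np.percentile(values, [25, 50, 75])
    return RoiSummary(
        median=float(med),
        p25=float(p25),
        p75=float(p75),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n=int(values.size),
    )


def long_format_table(summaries: dict[str, dict[str, "RoiSummary"]]):
    """Box-plot-ready long table from nested {subject: {parameter: RoiSummary}}.

    Returns a pandas DataFrame with columns (subject, parameter, statistic,
    value) — one row per summary statistic.
    """
    import pandas as pd

    rows = []
    for subject, per_param in summaries.items():
        for parameter, s in per_param.items():
            for stat in ("median", "p25", "p75", "mean", "sd"):
                rows.append(
                    {
                        "subject": subject,
                        "parameter": parameter,
                        "statistic": stat,
                        "value": getattr(s, stat),
                    }
                )
    return pd.DataFrame(rows, columns=["subject", "parameter", "statistic", "value"])


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    significant: bool
    degenerate: bool = False


def ga_trend(values: np.ndarray, ga_weeks: np.ndarray, *, alpha: float = 0.05) -> TrendResult:
    """Least-squares trend of per-subject values against gestational age.

    ``ga_weeks`` is in decimal weeks (weeks + days/7). Returns the fitted
    line, Pearson's r and its two-sided p-value; ``significant`` flags
    p < alpha. Constant values give slope 0 with r flagged degenerate.
    """
    values = np.asarray(values, float)
    ga = np.asarray(ga_weeks, float)
    if values.shape != ga.shape or values.ndim != 1:
        raise ValueError("values and ga_weeks must be 1-D and equal length")
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 subjects for a trend")
    if np.var(ga) == 0:
        raise ValueError("gestational ages have zero variance")
    if np.var(values) == 0:
        return TrendResult(0.0, float(values[0]), np.nan, np.nan, n, False, degenerate=True)
    slope, intercept, r, p, _ = stats.linregress(ga, values)
    return TrendResult(
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        p_value=float(p),
        n=n,
        significant=bool(p < alpha),
    )
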