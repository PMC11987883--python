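"""Descriptive and evaluation analyses of pre-farrowing activity.

Covers the correlation structure of a cohort (pairwise Pearson coefficients
and each subject's average correlation with the others), isolation of the
pre-farrowing activity rise from the diurnal cycle via STL decomposition,
per-day distribution statistics, interval-wise prediction reports, and a
simple return-on-investment calculator for a prediction system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from statsmodels.tsa.seasonal import STL

from .model import EvalMetrics, evaluate

__all__ = [
    "pcc", "correlation_matrix", "aacc", "stl_trend", "daily_stats",
    "interval_report", "roi", "RoiInputs", "DEFAULT_INTERVALS_H",
]

#: 6-hour evaluation bins over the last 30 h before onset, far to near
DEFAULT_INTERVALS_H: tuple[tuple[int, int], ...] = ((30, 24), (24, 18), (18, 12), (12, 6), (6, 0))


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient rho = cov(X, Y) / (sigma_X sigma_Y)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be equal-length 1-D with at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant series")
    return float(_sstats.pearsonr(x, y).statistic)


def correlation_matrix(series: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise Pearson matrix over subjects (rows = subjects)."""
    mat = np.asarray([np.asarray(s, dtype=np.float64) for s in series])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least two equal-length series")
    if (np.ptp(mat, axis=1) == 0).any():
        raise ValueError("Pearson correlation is undefined for a constant series")
    return np.corrcoef(mat)


def aacc(matrix: np.ndarray, denominator: str = "n_minus_1") -> np.ndarray:
    """Average activity correlation coefficient per subject.

    Row mean of the pairwise-correlation matrix excluding the diagonal.
    ``denominator='n_minus_1'`` (default) averages over the other subjects;
    ``'n'`` divides the off-diagonal sum by the total subject count instead.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8) or not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise ValueError("expected a symmetric correlation matrix with unit diagonal")
    if denominator not in ("n_minus_1", "n"):
        raise ValueError("denominator must be 'n_minus_1' or 'n'")
    n = m.shape[0]
    off_sum = m.sum(axis=1) - np.diag(m)
    return off_sum / (n - 1 if denominator == "n_minus_1" else n)


def stl_trend(series: Sequence[float], period: int = 288, robust: bool = False) -> np.ndarray:
    """Trend component of an additive STL decomposition.

    The series decomposes exactly into trend + seasonal + residual; only the
    trend is returned, which isolates the sustained pre-farrowing rise from
    the 24-hour cycle (``period=288`` at 5-minute resolution).  Loess window
    settings are the canonical STL defaults for the given period.
    """
    x = np.asarray(series, dtype=np.float64)
    if period < 2:
        raise ValueError("period must be >= 2")
    if len(x) < 2 * period:
        raise ValueError(f"series length {len(x)} must be >= 2 periods ({2 * period})")
    res = STL(x, period=period, robust=robust).fit()
    return np.asarray(res.trend)


def daily_stats(series: Sequence[float], points_per_day: int = 288) -> pd.DataFrame:
    """Per-day distribution statistics, days counted back from onset.

    Day 0 is the final ``points_per_day`` points (onset to 24 h before),
    day 1 the preceding block, and so on; a trailing partial block is
    dropped.  Quartiles use linear interpolation between order statistics.
    Columns: day, mean, min, max, q1, q2, q3, sd (sd is the sample SD).
    """
    x = np.asarray(series, dtype=np.float64)
    if points_per_day < 1:
        raise ValueError("points_per_day must be >= 1")
    n_days = len(x) // points_per_day
    if n_days == 0:
        raise ValueError("series shorter than one day block")
    rows = []
    for day in range(n_days):
        end = len(x) - day * points_per_day
        block = x[end - points_per_day : end]
        q1, q2, q3 = np.percentile(block, [25, 50, 75])
        rows.append({
            "day": day,
            "mean": block.mean(),
            "min": block.min(),
            "max": block.max(),
            "q1": q1,
            "q2": q2,
            "q3": q3,
            "sd": block.std(ddof=1) if len(block) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def interval_report(
    predictions: Sequence[float],
    labels: Sequence[float],
    intervals_h: Sequence[tuple[int, int]] = DEFAULT_INTERVALS_H,
) -> pd.DataFrame:
    """Per-interval prediction metrics over pre-onset time bins.

    Each ``(hi, lo)`` interval in hours covers labels in ``[lo*60, hi*60)``
    minutes (the 6-0 h bin therefore includes label 0).  Empty bins are kept
    in the table with NaN metrics and ``n=0`` rather than dropped.
    """
    yhat = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if yhat.shape != y.shape:
        raise ValueError("predictions and labels must align")
    rows = []
    for hi, lo in intervals_h:
        if hi <= lo:
            raise ValueError(f"interval ({hi}, {lo}) must run from later to earlier hours")
        mask = (y >= lo * 60) & (y < hi * 60)
        row = {"interval": f"{hi}-{lo}h", "hours_hi": hi, "hours_lo": lo, "n": int(mask.sum())}
        if mask.any() and np.ptp(y[mask]) > 0:
            m = evaluate(yhat[mask], y[mask])
            row.update(mae=m.mae, rmse=m.rmse, r2=m.r2)
        elif mask.any():
            err = y[mask] - yhat[mask]
            row.update(mae=float(np.abs(err).mean()),
                       rmse=float(np.sqrt((err**2).mean())), r2=np.nan)
        else:
            row.update(mae=np.nan, rmse=np.nan, r2=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RoiInputs:
    """Economic inputs for the return-on-investment calculator.

    piglets_saved (ΔP, per sow), piglet_value (V_p, currency), labor_hours_saved
    (ΔL, per sow), hourly_wage (W_l), equipment_cost (C_e) and operational_cost
    (C_o), all non-negative.
    """

    piglets_saved: float
    piglet_value: float
    labor_hours_saved: float
    hourly_wage: float
    equipment_cost: float
    operational_cost: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"RoiInputs.{name} must be non-negative, got {v}")


def roi(inputs: RoiInputs, cost_combine: str = "product") -> dict[str, float]:
    """Return-on-investment of a farrowing-prediction system.

    Benefits: B_p = ΔP · V_p (stillbirth-loss reduction) and B_l = ΔL · W_l
    (labor savings).  Total cost combines equipment and operational cost as
    a product (``cost_combine='product'``, the printed form) or a sum
    (``'sum'``, the economically standard reading).  ROI% = (B_p + B_l −
    C_total) / C_total · 100.
    """
    if cost_combine not in ("product", "sum"):
        raise ValueError("cost_combine must be 'product' or 'sum'")
    b_p = inputs.piglets_saved * inputs.piglet_value
    b_l = inputs.labor_hours_saved * inputs.hourly_wage
    if cost_combine == "product":
        c_total = inputs.equipment_cost * inputs.operational_cost
    else:
        c_total = inputs.equipment_cost + inputs.operational_cost
    if c_total <= 0:
        raise ValueError("total implementation cost must be positive")
    return {
        "B_p": b_p,
        "B_l": b_l,
        "C_total": c_total,
        "roi_percent": (b_p + b_l - c_total) / c_total * 100.0,
    }
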