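"""Single-breakpoint segmented trend classification.

Every candidate partition into two contiguous segments is scanned
exhaustively; the break minimizing total residual sum of squares is compared
against the no-break linear fit by BIC. Retained segments are classified as
increasing / decreasing / no trend from segment-local OLS slope tests.

The reported ``breakpoint_year`` is the first year of the second segment,
i.e. the year in which the new regime applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AnnualSeries

__all__ = ["SegmentFit", "TrendResult", "fit_segmented", "trend_table"]

_RSS_FLOOR = 1e-30


@dataclass(frozen=True)
class SegmentFit:
    start_year: int
    end_year: int
    n: int
    slope: float
    p_value: float
    direction: str            # increasing | decreasing | no trend
    short_segment: bool = False  # df < 2: p-value unreliable


@dataclass(frozen=True)
class TrendResult:
    variable: str
    breakpoint_year: int | None
    segments: tuple
    bic_null: float
    bic_break: float
    selected_model: str       # "null" or "break"

    def __post_init__(self):
        want_break = self.bic_break < self.bic_null
        if (self.selected_model == "break") != want_break:
            raise ValueError("selected_model inconsistent with BIC values")


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _segment_fit(years: np.ndarray, values: np.ndarray, alpha: float) -> SegmentFit:
    n = years.size
    if np.ptp(values) == 0:
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(years.astype(float), values)
        slope, p = float(fit.slope), float(fit.pvalue)
        if math.isnan(p):
            p = 1.0
    if p < alpha and slope > 0:
        direction = "increasing"
    elif p < alpha and slope < 0:
        direction = "decreasing"
    else:
        direction = "no trend"
    return SegmentFit(int(years[0]), int(years[-1]), n, slope, p, direction,
                      short_segment=n - 2 < 2)


def default_min_segment(n: int) -> int:
    """Trimming rule: at least 3 points and 15% of the series per segment."""
    return max(3, math.ceil(0.15 * n))


def fit_segmented(series: AnnualSeries, min_segment: int | None = None,
                  alpha: float = 0.05) -> TrendResult:
    years = series.years
    values = series.values
    if np.isnan(values).any():
        raise ValueError(f"{series.name}: missing values; interpolate first")
    n = years.size
    if min_segment is None:
        min_segment = default_min_segment(n)
    if n < 2 * min_segment:
        raise ValueError(f"{series.name}: need >= {2 * min_segment} points, got {n}")

    x = years.astype(float)
    rss_null = _ols_rss(x, values)
    # BIC with Gaussian errors; k counts intercepts, slopes, error variance,
    # and (for the break model) the break position. RSS is floored relative
    # to the series scale so numerically-zero fits compare by penalty alone.
    tss = float(np.sum((values - values.mean()) ** 2))
    floor = max(1e-10 * tss, _RSS_FLOOR)
    bic_null = n * math.log(max(rss_null, floor) / n) + 3 * math.log(n)

    # ties (within numerical noise of the series scale) go to the earlier year
    tol = 1e-9 * max(rss_null, 1.0)
    best_rss, best_split = math.inf, None
    for split in range(min_segment, n - min_segment + 1):
        rss = _ols_rss(x[:split], values[:split]) + _ols_rss(x[split:], values[split:])
        if best_split is None or rss < best_rss - tol:
            best_rss, best_split = rss, split
    bic_break = n * math.log(max(best_rss, floor) / n) + 6 * math.log(n)

    if bic_break < bic_null:
        split = best_split
        segments = (_segment_fit(years[:split], values[:split], alpha),
                    _segment_fit(years[split:], values[split:], alpha))
        return TrendResult(series.name, int(years[split]), segments,
                           bic_null, bic_break, "break")
    segments = (_segment_fit(years, values, alpha),)
    return TrendResult(series.name, None, segments, bic_null, bic_break, "null")


def trend_table(results: list[TrendResult]) -> pd.DataFrame:
    """Flat results table, one row per (variable, segment)."""
    rows = []
    for res in results:
        for i, seg in enumerate(res.segments):
            rows.append({
                "variable": res.variable,
                "selected_model": res.selected_model,
                "breakpoint_year": res.breakpoint_year,
                "segment": i + 1,
                "start_year": seg.start_year,
                "end_year": seg.end_year,
                "slope": seg.slope,
                "p_value": seg.p_value,
                "direction": seg.direction,
                "short_segment": seg.short_segment,
                "bic_null": res.bic_null,
                "bic_break": res.bic_break,
            })
    return pd.DataFrame(rows)
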