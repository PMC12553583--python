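"""Annual-series preprocessing: aggregation, covariate adjustment,
interpolation, standardization and detrending.

The canonical stage order for a series feeding the regression stages is

    aggregate -> adjust -> interpolate -> zscore -> detrend

and every stage stamps a flag onto the series so downstream code can verify
provenance (see :data:`FLAG_ORDER`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnualSeries",
    "AdjustmentModel",
    "FLAG_ORDER",
    "FISH_COLUMNS",
    "load_tef_table",
    "validate_fish_table",
    "read_fish_csv",
    "read_predictor_csv",
    "lipid_normalize",
    "compute_teq",
    "annual_aggregate",
    "fit_covariate_adjustment",
    "adjust_values",
    "stineman_interpolate",
    "zscore",
    "detrend",
]

#: Flags in the order the pipeline applies them; a later flag implies the
#: earlier stages already ran.
FLAG_ORDER = ("aggregated", "adjusted", "interpolated", "zscored", "detrended")

#: Column registry for the individual-fish table (units documented, not converted).
FISH_COLUMNS = {
    "year": "calendar year",
    "total_length": "cm",
    "age": "yr",
    "lipid_fraction": "fraction (0-1]",
    "conc_cb153": "ug/g lipid wt",
    "conc_hg": "ng/g wet wt",
    "teq_pcddf": "pg TEQ/g lipid wt (optional)",
    "d13c": "permil",
    "d15n": "permil",
}

_REQUIRED_FISH_COLUMNS = ("year", "total_length", "age", "lipid_fraction")


@dataclass(frozen=True)
class AnnualSeries:
    """One year-indexed variable with units, missing mask and provenance flags.

    ``values`` uses NaN for missing years; ``years`` must be strictly
    increasing.
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or values.ndim != 1 or years.size != values.size:
            raise ValueError("years and values must be 1-D and equal length")
        if years.size > 1 and not np.all(np.diff(years) > 0):
            raise ValueError(f"{self.name}: years must be strictly increasing")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n(self) -> int:
        return int(np.sum(~self.missing_mask))

    def with_values(self, values: np.ndarray, add_flags: Iterable[str] = ()) -> "AnnualSeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       flags=self.flags | frozenset(add_flags))

    def require_flags(self, *needed: str) -> None:
        missing = [f for f in needed if f not in self.flags]
        if missing:
            raise ValueError(
                f"series {self.name!r} lacks required processing stage(s): {missing}; "
                f"present flags: {sorted(self.flags)}")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"),
                         name=self.name)


@dataclass(frozen=True)
class AdjustmentModel:
    """OLS covariate-adjustment model: slope ``a``, covariate mean, fit stats."""

    a: float
    covariate_mean: float
    r2: float
    p_value: float
    applied: bool
    alpha: float = 0.05

    def __post_init__(self):
        if self.applied and not self.p_value < self.alpha:
            raise ValueError("applied adjustment requires p_value < alpha")


def load_tef_table() -> dict[str, float]:
    """Packaged WHO-2005 TEF table as ``{congener: factor}`` (17 entries)."""
    path = resources.files("contamdrivers.data").joinpath("tef_who2005.csv")
    with path.open() as fh:
        table = pd.read_csv(fh, comment="#")
    tefs = dict(zip(table["congener"], table["tef"].astype(float)))
    _validate_tefs(tefs)
    return tefs


def _validate_tefs(tefs: Mapping[str, float]) -> None:
    if len(tefs) != 17:
        raise ValueError(f"TEF table must have 17 congeners, got {len(tefs)}")
    bad = {k: v for k, v in tefs.items() if not (0 < v <= 1)}
    if bad:
        raise ValueError(f"TEF values must lie in (0, 1]: {bad}")


def validate_fish_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_FISH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fish table missing required columns: {missing}")
    if (table["total_length"] <= 0).any():
        raise ValueError("total_length must be > 0")
    if (table["age"] < 0).any():
        raise ValueError("age must be >= 0")
    lipid = table["lipid_fraction"]
    if ((lipid <= 0) | (lipid > 1)).any():
        raise ValueError("lipid_fraction must lie in (0, 1]")
    for col in ("conc_cb153", "conc_hg", "teq_pcddf"):
        if col in table.columns and (table[col].dropna() < 0).any():
            raise ValueError(f"{col} must be >= 0")
    return table


def read_fish_csv(path) -> pd.DataFrame:
    return validate_fish_table(pd.read_csv(path))


def read_predictor_csv(path) -> pd.DataFrame:
    """Annual predictor table: a ``year`` column plus one column per predictor."""
    table = pd.read_csv(path)
    if "year" not in table.columns:
        raise ValueError("predictor table must have a 'year' column")
    table = table.set_index("year").sort_index()
    if table.index.duplicated().any():
        raise ValueError("duplicate years in predictor table")
    return table


# ---------------------------------------------------------------------------
# scalar / per-record operations


def lipid_normalize(conc_wet, lipid_fraction):
    """Convert a wet-weight concentration to lipid-weight basis."""
    lipid_fraction = np.asarray(lipid_fraction, dtype=float)
    if np.any(lipid_fraction <= 0):
        raise ValueError("lipid_fraction must be > 0")
    return np.asarray(conc_wet, dtype=float) / lipid_fraction


def compute_teq(congeners: Mapping[str, float], lods: Mapping[str, float],
                tefs: Mapping[str, float]) -> float:
    """Lower-bound TEQ: concentrations below their LOD contribute zero."""
    _validate_tefs(tefs)
    unknown = sorted(set(congeners) - set(tefs))
    if unknown:
        raise KeyError(f"congener(s) without a TEF: {unknown}")
    total = 0.0
    for name, conc in congeners.items():
        lod = lods.get(name, 0.0)
        if conc >= lod:
            total += tefs[name] * conc
    return total


# ---------------------------------------------------------------------------
# annual series construction


def annual_aggregate(records: pd.DataFrame, variable: str, method: str = "geometric",
                     units: str = "") -> AnnualSeries:
    """Collapse per-individual records to one value per sampled year.

    ``method='geometric'`` computes exp(mean(log x)) and requires strictly
    positive values; ``'arithmetic'`` is the plain mean (used for delta
    values, which may be negative).
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregation method {method!r}")
    sub = records[["year", variable]].dropna()
    years = np.sort(sub["year"].unique())
    out = np.empty(years.size)
    for i, yr in enumerate(years):
        vals = sub.loc[sub["year"] == yr, variable].to_numpy(dtype=float)
        if method == "geometric":
            if np.any(vals <= 0):
                raise ValueError(
                    f"geometric mean undefined for non-positive {variable!r} in year {yr}")
            out[i] = float(np.exp(np.mean(np.log(vals))))
        else:
            out[i] = float(np.mean(vals))
    return AnnualSeries(variable, years, out, units=units, flags={"aggregated"})


def fit_covariate_adjustment(values, covariate, alpha: float = 0.05) -> AdjustmentModel:
    """OLS of ``values ~ covariate``; the adjustment is applied iff p < alpha."""
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.size != covariate.size or values.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate has zero variance")
    if np.ptp(values) == 0:
        # degenerate response: slope 0, nothing to adjust
        return AdjustmentModel(0.0, float(np.mean(covariate)), 0.0, 1.0, False, alpha)
    fit = stats.linregress(covariate, values)
    p = float(fit.pvalue)
    return AdjustmentModel(float(fit.slope), float(np.mean(covariate)),
                           float(fit.rvalue**2), p, applied=p < alpha, alpha=alpha)


def adjust_values(values, covariate, model: AdjustmentModel) -> np.ndarray:
    """Shift each value to what it would be at the covariate's series mean:
    ``adjusted = measured + a * (cov_mean - cov_measured)``."""
    if not model.applied:
        raise ValueError("adjustment model was not significant; refuse to apply")
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    return values + model.a * (model.covariate_mean - covariate)


# ---------------------------------------------------------------------------
# Stineman (1980) rational interpolation


def _stineman_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tangent slopes at data points from the circle through each point and
    its two neighbours (secant slope where the three points are collinear)."""
    n = x.size
    s = np.diff(y) / np.diff(x)
    yp = np.empty(n)

    def circle_slope(i0, i1, i2, at):
        x0, x1, x2 = x[i0], x[i1], x[i2]
        y0, y1, y2 = y[i0], y[i1], y[i2]
        d = 2.0 * (x0 * (y1 - y2) + x1 * (y2 - y0) + x2 * (y0 - y1))
        span = max(np.ptp(x[[i0, i1, i2]]), np.ptp(y[[i0, i1, i2]]), 1.0)
        if abs(d) < 1e-12 * span**2:  # collinear
            return None
        q0 = x0 * x0 + y0 * y0
        q1 = x1 * x1 + y1 * y1
        q2 = x2 * x2 + y2 * y2
        cx = (q0 * (y1 - y2) + q1 * (y2 - y0) + q2 * (y0 - y1)) / d
        cy = (q0 * (x2 - x1) + q1 * (x0 - x2) + q2 * (x1 - x0)) / d
        if abs(y[at] - cy) < 1e-12 * span:  # vertical tangent
            return None
        return -(x[at] - cx) / (y[at] - cy)

    for i in range(1, n - 1):
        slope = circle_slope(i - 1, i, i + 1, i)
        if slope is None:
            h0, h1 = x[i] - x[i - 1], x[i + 1] - x[i]
            slope = (s[i - 1] * h1 + s[i] * h0) / (h0 + h1)
        yp[i] = slope
    if n == 2:
        yp[:] = s[0]
        return yp
    first = circle_slope(0, 1, 2, 0)
    yp[0] = first if first is not None else s[0]
    last = circle_slope(n - 3, n - 2, n - 1, n - 1)
    yp[-1] = last if last is not None else s[-1]
    return yp


def _stineman_eval(xk: np.ndarray, yk: np.ndarray, yp: np.ndarray,
                   xi: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(xk, xi, side="right") - 1, 0, xk.size - 2)
    x1, x2 = xk[idx], xk[idx + 1]
    y1, y2 = yk[idx], yk[idx + 1]
    s = (y2 - y1) / (x2 - x1)
    yo = y1 + s * (xi - x1)
    dy1 = (yp[idx] - s) * (xi - x1)
    dy2 = (yp[idx + 1] - s) * (xi - x2)
    prod = dy1 * dy2
    out = yo.copy()
    pos = prod > 0
    out[pos] = yo[pos] + prod[pos] / (dy1[pos] + dy2[pos])
    neg = prod < 0
    out[neg] = yo[neg] + prod[neg] * (2.0 * xi[neg] - x1[neg] - x2[neg]) / (
        (dy1[neg] - dy2[neg]) * (x2[neg] - x1[neg]))
    return out


def stineman_interpolate(series: AnnualSeries) -> AnnualSeries:
    """Fill interior missing years by Stineman rational interpolation.

    Observed values are untouched; leading/trailing gaps raise (no
    extrapolation).
    """
    mask = series.missing_mask
    if not mask.any():
        return series.with_values(series.values, add_flags={"interpolated"})
    if mask[0] or mask[-1]:
        raise ValueError(
            f"series {series.name!r} has leading/trailing missing years; "
            "interpolation does not extrapolate")
    if series.n < 3:
        raise ValueError("need >= 3 observed points to interpolate")
    xk = series.years[~mask].astype(float)
    yk = series.values[~mask]
    yp = _stineman_slopes(xk, yk)
    out = series.values.copy()
    out[mask] = _stineman_eval(xk, yk, yp, series.years[mask].astype(float))
    return series.with_values(out, add_flags={"interpolated"})


# ---------------------------------------------------------------------------
# standardization and detrending


def zscore(series: AnnualSeries) -> AnnualSeries:
    """Mean-centre and scale to unit sample SD (n-1 denominator)."""
    vals = series.values
    if np.isnan(vals).any():
        raise ValueError(f"series {series.name!r} has missing values; interpolate first")
    if vals.size < 2:
        raise ValueError("need >= 2 values")
    sd = np.std(vals, ddof=1)
    if sd == 0:
        raise ValueError(f"series {series.name!r} has zero variance")
    return series.with_values((vals - np.mean(vals)) / sd, add_flags={"zscored"})


def detrend(series: AnnualSeries) -> AnnualSeries:
    """Remove the linear time trend while preserving the series mean.

    Returns ``value + a * (mean(year) - year)`` with ``a`` the OLS slope
    against year — identical to OLS residuals plus the series mean.
    """
    vals = series.values
    if np.isnan(vals).any():
        raise ValueError(f"series {series.name!r} has missing values; interpolate first")
    if vals.size < 3:
        raise ValueError("need >= 3 values")
    years = series.years.astype(float)
    if np.ptp(vals) == 0:
        a = 0.0
    else:
        a = float(stats.linregress(years, vals).slope)
    out = vals + a * (np.mean(years) - years)
    return series.with_values(out, add_flags={"detrended"})
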