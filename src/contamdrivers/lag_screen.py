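"""Cross-correlation screening of lagged predictor effects.

ccf(k) is the Pearson correlation of the predictor at year t-k with the
response at year t; lags 0..max_lag are screened against the usual
1.96/sqrt(n) bound. Significant lags >= 1 become extra columns
``<predictor>_lag<k>`` in the analysis matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AnnualSeries

__all__ = ["LagSpec", "cross_correlation", "build_lagged_matrix",
           "lag_table", "LAG_COLUMN_RE"]

LAG_COLUMN_RE = re.compile(r"^(?P<base>.+)_lag(?P<lag>[1-9]\d*)$")


@dataclass(frozen=True)
class LagSpec:
    predictor: str
    lag: int
    ccf: float
    bound: float
    significant: bool

    def __post_init__(self):
        if self.significant != (abs(self.ccf) > self.bound):
            raise ValueError("significance flag inconsistent with |ccf| vs bound")

    @property
    def column_name(self) -> str:
        return f"{self.predictor}_lag{self.lag}" if self.lag else self.predictor


def _aligned_values(x: AnnualSeries, y: AnnualSeries) -> tuple[np.ndarray, np.ndarray]:
    if not np.array_equal(x.years, y.years):
        raise ValueError("series must cover identical years")
    return x.values, y.values


def cross_correlation(x: AnnualSeries, y: AnnualSeries, max_lag: int = 5) -> list[LagSpec]:
    """Screen lags 0..max_lag of predictor ``x`` against response ``y``."""
    xv, yv = _aligned_values(x, y)
    n = xv.size
    if n < 8:
        raise ValueError("need >= 8 aligned years")
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("missing values; interpolate first")
    bound = 1.96 / np.sqrt(n)
    specs = []
    for k in range(max_lag + 1):
        xs = xv[: n - k] if k else xv
        ys = yv[k:]
        if xs.size < 4:
            warnings.warn(f"{x.name}: lag {k} overlap < 4 years; omitted")
            continue
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(xs, ys)[0, 1])
        specs.append(LagSpec(x.name, k, r, float(bound), abs(r) > bound))
    return specs


def build_lagged_matrix(X: pd.DataFrame, specs: list[LagSpec]) -> pd.DataFrame:
    """Append one shifted column per significant lag >= 1 and drop the years
    for which a lagged value is unavailable.

    The drop is reported via the returned frame's ``attrs['dropped_years']``.
    """
    keyset = {(s.predictor, s.lag) for s in specs}
    if len(keyset) != len(specs):
        raise ValueError("duplicate lag specs")
    out = X.copy()
    for spec in specs:
        if spec.lag == 0 or not spec.significant:
            continue
        if spec.predictor not in X.columns:
            raise KeyError(f"unknown predictor {spec.predictor!r}")
        if spec.column_name in out.columns:
            raise ValueError(f"duplicate lagged column {spec.column_name!r}")
        out[spec.column_name] = X[spec.predictor].shift(spec.lag)
    kept = out.dropna()
    kept.attrs["dropped_years"] = [int(y) for y in out.index.difference(kept.index)]
    return kept


def lag_table(specs: list[LagSpec]) -> pd.DataFrame:
    return pd.DataFrame([{
        "predictor": s.predictor, "lag": s.lag, "ccf": s.ccf,
        "bound": s.bound, "significant": s.significant,
    } for s in specs])
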