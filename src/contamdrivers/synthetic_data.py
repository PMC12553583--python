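"""Synthetic monitoring-data generator with known ground truth.

Produces annual predictor matrices (linear trends, optional single slope
change, white or AR(1) noise), individual-fish tables whose log-scale
contaminant response is a linear function of detrended, possibly lagged
predictors, and congener panels with below-LOD flags. Every output is
deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import load_tef_table

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_predictors",
           "generate_fish", "generate_congener_panel", "write_bundle"]


@dataclass(frozen=True)
class SyntheticConfig:
    year_start: int = 1995
    year_end: int = 2018
    n_fish_per_year: int = 12
    tl_mean: float = 17.7
    tl_sd: float = 1.0
    tl_range: tuple = (15.0, 19.0)
    age_levels: tuple = (3, 4, 5)
    age_tl_slope: float = 0.5        # yr per cm
    n_predictors: int = 14
    trend_slopes: tuple | None = None      # z-units / yr, one per predictor
    breakpoints: dict = field(default_factory=dict)  # name -> (year, extra slope)
    true_coefficients: dict = field(default_factory=dict)  # name -> z-effect
    true_lags: dict = field(default_factory=dict)          # name -> lag in {0..5}
    response_trend_slope: float = -0.03    # log-units / yr
    age_effect: float = 0.0                # log-units per year of age
    noise_sd: float = 0.3                  # response noise, log-units
    predictor_noise_sd: float | None = None  # defaults to noise_sd
    ar1_phi: float = 0.0                   # optional AR(1) predictor noise
    isotope_cov: tuple = ((1.0, 0.3), (0.3, 0.5))
    missing_years: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.year_end - self.year_start < 9:
            raise ValueError("need at least a 10-year span")
        if self.n_fish_per_year < 3:
            raise ValueError("n_fish_per_year must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(not (0 <= lag <= 5) for lag in self.true_lags.values()):
            raise ValueError("true lags must lie in 0..5")
        for name, (year, _) in self.breakpoints.items():
            if not (self.year_start < year <= self.year_end):
                raise ValueError(f"breakpoint for {name!r} at {year} outside year range")
        object.__setattr__(self, "missing_years", frozenset(self.missing_years))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def predictor_names(self) -> tuple:
        return tuple(f"pred{j + 1:02d}" for j in range(self.n_predictors))


@dataclass(frozen=True)
class SyntheticTruth:
    true_coefficients: dict
    true_lags: dict
    breakpoint_map: dict
    driver_ranking: tuple   # names ordered by decreasing |coefficient|

    def to_json(self) -> str:
        payload = asdict(self)
        payload["driver_ranking"] = list(self.driver_ranking)
        return json.dumps(payload, indent=2, sort_keys=True)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator call
    return np.random.default_rng([config.seed, stream])


def generate_predictors(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Annual predictor matrix (years x predictors) plus the truth object."""
    rng = _rng(config, 0)
    years = config.years
    t = years - years[0]
    names = config.predictor_names
    slopes = config.trend_slopes or (0.0,) * config.n_predictors
    if len(slopes) != config.n_predictors:
        raise ValueError("trend_slopes length must equal n_predictors")
    unknown = set(config.breakpoints) - set(names)
    if unknown:
        raise ValueError(f"breakpoints for unknown predictors: {sorted(unknown)}")
    noise_sd = (config.noise_sd if config.predictor_noise_sd is None
                else config.predictor_noise_sd)

    data = {}
    for name, slope in zip(names, slopes):
        series = slope * t.astype(float)
        if name in config.breakpoints:
            b_year, extra = config.breakpoints[name]
            series = series + extra * np.clip(years - b_year, 0, None)
        eps = rng.normal(0.0, noise_sd, size=years.size) if noise_sd > 0 \
            else np.zeros(years.size)
        if config.ar1_phi:
            for i in range(1, eps.size):
                eps[i] += config.ar1_phi * eps[i - 1]
        data[name] = series + eps
    X = pd.DataFrame(data, index=pd.Index(years, name="year"))

    coefs = {n: float(config.true_coefficients.get(n, 0.0)) for n in names}
    lags = {n: int(config.true_lags.get(n, 0)) for n in names}
    ranking = tuple(sorted(names, key=lambda n: (-abs(coefs[n]), n)))
    truth = SyntheticTruth(coefs, lags, dict(config.breakpoints), ranking)
    return X, truth


def _detrended(col: np.ndarray, years: np.ndarray) -> np.ndarray:
    if np.ptp(col) == 0:
        return col - col.mean()
    slope, intercept = np.polyfit(years.astype(float), col, 1)
    return col - (intercept + slope * years)


def year_signal(config: SyntheticConfig, predictors: pd.DataFrame,
                truth: SyntheticTruth) -> tuple[pd.Series, pd.Series]:
    """Deterministic annual log-response component and a flag series marking
    years whose lagged term reached before the start of the series."""
    years = predictors.index.to_numpy()
    detr = {n: _detrended(predictors[n].to_numpy(float), years)
            for n in predictors.columns}
    pos = {int(y): i for i, y in enumerate(years)}
    signal = config.response_trend_slope * (years - years.mean())
    truncated = np.zeros(years.size, dtype=bool)
    for name, coef in truth.true_coefficients.items():
        if coef == 0.0:
            continue
        lag = truth.true_lags.get(name, 0)
        for i, y in enumerate(years):
            src = int(y) - lag
            if src in pos:
                signal[i] += coef * detr[name][pos[src]]
            else:
                truncated[i] = True   # lagged term unavailable: contributes zero
    return (pd.Series(signal, index=predictors.index),
            pd.Series(truncated, index=predictors.index))


def generate_fish(config: SyntheticConfig, predictors: pd.DataFrame,
                  truth: SyntheticTruth) -> pd.DataFrame:
    """Individual-fish table with TL, age correlated with TL, log-linear
    contaminant response and bivariate-normal bulk isotopes."""
    if not set(map(int, config.years)) <= set(map(int, predictors.index)):
        raise ValueError("predictors must cover all configured years")
    rng = _rng(config, 1)
    signal, truncated = year_signal(config, predictors, truth)

    lo, hi = config.tl_range
    a = (lo - config.tl_mean) / config.tl_sd
    b = (hi - config.tl_mean) / config.tl_sd
    ages = np.asarray(sorted(config.age_levels))
    age_mid = float(np.mean(ages))
    iso_cov = np.asarray(config.isotope_cov, dtype=float)

    rows = []
    for year in config.years:
        if int(year) in config.missing_years:
            continue
        tl = stats.truncnorm.rvs(a, b, loc=config.tl_mean, scale=config.tl_sd,
                                 size=config.n_fish_per_year, random_state=rng)
        # age from TL with jitter: keeps the age~TL regression significant
        # without a growth model
        age_raw = age_mid + config.age_tl_slope * (tl - config.tl_mean) \
            + rng.normal(0.0, 0.4, size=tl.size)
        age = ages[np.clip(np.searchsorted(
            (ages[:-1] + ages[1:]) / 2.0, age_raw), 0, ages.size - 1)]
        base = float(signal.loc[int(year)])
        log_conc = base + config.age_effect * (age - age_mid) \
            + rng.normal(0.0, config.noise_sd, size=tl.size)
        iso_mean = np.array([-21.0 + 0.02 * (year - config.year_start),
                             11.0 - 0.01 * (year - config.year_start)])
        iso = rng.multivariate_normal(iso_mean, iso_cov, size=tl.size)
        lipid = rng.uniform(0.02, 0.06, size=tl.size)
        for k in range(tl.size):
            rows.append({
                "year": int(year),
                "total_length": float(tl[k]),
                "age": int(age[k]),
                "lipid_fraction": float(lipid[k]),
                "conc_cb153": float(np.exp(log_conc[k])),
                "conc_hg": float(np.exp(3.5 + 0.8 * log_conc[k])),
                "d13c": float(iso[k, 0]),
                "d15n": float(iso[k, 1]),
                "lag_truncated": bool(truncated.loc[int(year)]),
            })
    return pd.DataFrame(rows)


def generate_congener_panel(config: SyntheticConfig, seed: int | None = None,
                            n_samples_per_year: int = 2,
                            below_lod_fraction: float = 0.2) -> pd.DataFrame:
    """Panel of the 17 TEF congeners with concentrations (pg/g), LOD values
    and below-LOD flags; exactly floor(fraction * n) entries per congener are
    flagged (the lowest concentrations)."""
    if not 0.0 <= below_lod_fraction <= 1.0:
        raise ValueError("below_lod_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    congeners = list(load_tef_table())
    years = np.repeat(config.years, n_samples_per_year)
    panel = {"year": years, "sample": np.tile(
        np.arange(n_samples_per_year), config.years.size)}
    n = years.size
    n_flag = int(np.floor(below_lod_fraction * n))
    if below_lod_fraction >= 1.0:
        n_flag = n
    for name in congeners:
        conc = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        order = np.argsort(conc)
        flags = np.zeros(n, dtype=bool)
        flags[order[:n_flag]] = True
        if n_flag == 0:
            lod = 0.0
        elif n_flag == n:
            lod = float(conc.max()) * 2.0
        else:
            lod = float((conc[order[n_flag - 1]] + conc[order[n_flag]]) / 2.0)
        panel[f"conc_{name}"] = conc
        panel[f"lod_{name}"] = np.full(n, lod)
        panel[f"below_lod_{name}"] = flags
    return pd.DataFrame(panel)


def write_bundle(config: SyntheticConfig, out_dir) -> dict:
    """Write fish/predictor/congener CSVs (RFC 4180, UTF-8) and truth JSON;
    returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, truth = generate_predictors(config)
    fish = generate_fish(config, X, truth)
    panel = generate_congener_panel(config)
    paths = {
        "predictors": out_dir / "predictors.csv",
        "fish": out_dir / "fish.csv",
        "congeners": out_dir / "congeners.csv",
        "truth": out_dir / "truth.json",
    }
    X.reset_index().to_csv(paths["predictors"], index=False, encoding="utf-8",
                           lineterminator="\r\n")
    fish.to_csv(paths["fish"], index=False, encoding="utf-8", lineterminator="\r\n")
    panel.to_csv(paths["congeners"], index=False, encoding="utf-8",
                 lineterminator="\r\n")
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
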