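"""Single-response partial least squares (NIPALS PLS1) with leave-one-out
validation, VIP-based backward elimination, weighted-regression-coefficient
(WRC) importance ranking, permutation validation and residual diagnostics.

All fitting is done on internally standardized X and y (training-fold
statistics during cross-validation); predictions are returned on the raw
response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.stattools import acf as _acf

from .lag_screen import LAG_COLUMN_RE

__all__ = [
    "PLSRModel", "SelectionTrace", "PermutationResult",
    "nipals_fit", "loo_q2", "select_components", "vip", "wrc",
    "backward_select", "permutation_test", "residual_autocorrelation",
    "collinearity_screen", "model_quality",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PLSRModel:
    """Fitted PLS1 model on standardized scales.

    weights (p x A, unit-norm columns), x_loadings (p x A), scores (n x A),
    y_loadings (A,), coefficients (p,) on the standardized scale; r2y / q2 /
    press indexed by cumulative component count. q2/press are NaN until
    cross-validation results are attached.
    """

    predictor_names: tuple
    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    r2y: np.ndarray
    ssy: np.ndarray            # explained y-variance per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    q2: np.ndarray | None = None
    press: np.ndarray | None = None

    @property
    def vip(self) -> np.ndarray:
        return vip(self)

    @property
    def wrc(self) -> np.ndarray:
        return wrc(self)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.predictor_names)
        Xs = (X - self.x_mean) / self.x_scale
        return (Xs @ self.coefficients) * self.y_scale + self.y_mean

    def with_cv(self, q2: np.ndarray, press: np.ndarray) -> "PLSRModel":
        from dataclasses import replace
        return replace(self, q2=np.asarray(q2, float), press=np.asarray(press, float))


@dataclass(frozen=True)
class SelectionTrace:
    steps: tuple            # (dropped predictor, vip at drop, q2 after refit)
    final_predictors: tuple
    lag_decisions: tuple = ()   # (column, delta_q2, retained)


@dataclass(frozen=True)
class PermutationResult:
    observed_q2: float
    observed_r2y: float
    null_q2: np.ndarray
    null_r2y: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def _as_matrix(X, names=None):
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X.loc[:, list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _names(X, p):
    if isinstance(X, pd.DataFrame):
        return tuple(map(str, X.columns))
    return tuple(f"x{j}" for j in range(p))


def _standardize_columns(M, what="X"):
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd < _EPS):
        idx = np.flatnonzero(sd < _EPS)
        raise ValueError(f"zero-variance {what} column(s) at index {idx.tolist()}")
    return (M - mean) / sd, mean, sd


def nipals_fit(X, y, n_components: int) -> PLSRModel:
    """Classical PLS1 NIPALS.

    Per component: w = X'y normalized, t = Xw, p = X't/(t't), q = y't/(t't),
    then X and y are deflated. Coefficients b = W (P'W)^-1 q.
    """
    names = _names(X, np.shape(X)[1])
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if yv.size != n:
        raise ValueError("X and y length mismatch")
    if n < n_components + 2:
        raise ValueError(f"need n >= A+2 (n={n}, A={n_components})")
    Xs, x_mean, x_scale = _standardize_columns(Xm, "X")
    ys_full, y_mean, y_scale = _standardize_columns(yv[:, None], "y")
    ys = ys_full.ravel()
    if n_components > np.linalg.matrix_rank(Xs):
        raise ValueError(f"A={n_components} exceeds rank of X")

    tss = float(ys @ ys)
    Xd, yd = Xs.copy(), ys.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    r2y = np.zeros(n_components)
    ssy = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < _EPS:   # no covariance left to model
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        ssy[a] = qa**2 * tt
        r2y[a] = 1.0 - float(yd @ yd) / tss
        a_used = a + 1

    W, P, T, q = W[:, :a_used], P[:, :a_used], T[:, :a_used], q[:a_used]
    r2y, ssy = r2y[:a_used], ssy[:a_used]
    if a_used:
        b = W @ np.linalg.solve(P.T @ W, q)
    else:
        b = np.zeros(p)
    return PLSRModel(names, a_used, W, P, T, q, b, r2y, ssy,
                     x_mean, x_scale, float(y_mean[0]), float(y_scale[0]))


def loo_q2(X, y, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out Q^2 and PRESS per cumulative component count.

    Each fold standardizes on its training data, fits NIPALS and predicts
    the left-out observation; TSS accumulates squared deviations from the
    training-fold means.
    """
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    if n < 6:
        raise ValueError("need n >= 6 for leave-one-out")
    A = min(n_components, n - 3)  # training fold needs n-1 >= A+2
    press = np.zeros(A)
    tss = 0.0
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        model = nipals_fit(Xm[keep], yv[keep], A)
        tss += (yv[i] - np.mean(yv[keep])) ** 2
        xs = (Xm[i] - model.x_mean) / model.x_scale
        # cumulative prediction per component from the deflation recursion
        b_prev = np.zeros(Xm.shape[1])
        for a in range(A):
            if a < model.n_components:
                Wa = model.weights[:, : a + 1]
                Pa = model.x_loadings[:, : a + 1]
                qa = model.y_loadings[: a + 1]
                b_prev = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
            pred = (xs @ b_prev) * model.y_scale + model.y_mean
            press[a] += (yv[i] - pred) ** 2
    q2 = 1.0 - press / tss
    return q2, press


def select_components(X, y, a_max: int | None = None, press_tol: float = 0.05) -> int:
    """Smallest component count whose PRESS is within ``press_tol`` of the
    minimum over 1..a_max."""
    Xm = _as_matrix(X)
    n, p = Xm.shape
    cap = min(n - 3, p)
    a_max = cap if a_max is None else min(a_max, cap)
    a_max = max(a_max, 1)
    _, press = loo_q2(Xm, y, a_max)
    best = float(np.min(press))
    ok = np.flatnonzero(press <= (1.0 + press_tol) * best)
    return int(ok[0]) + 1


def vip(model: PLSRModel) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ); sum VIP^2 = p."""
    p = len(model.predictor_names)
    if model.n_components == 0:
        return np.full(p, np.nan)
    ssy = model.ssy
    return np.sqrt(p * (model.weights**2 @ ssy) / ssy.sum())


def wrc(model: PLSRModel) -> np.ndarray:
    """Signed importance: coefficient times summed squared component weights."""
    return model.coefficients * (model.weights**2).sum(axis=1)


def _fit_with_cv(X, y, a_max=None, press_tol=0.05):
    a_star = select_components(X, y, a_max=a_max, press_tol=press_tol)
    model = nipals_fit(X, y, a_star)
    q2, press = loo_q2(X, y, a_star)
    return model.with_cv(q2, press)


def backward_select(X: pd.DataFrame, y, vip_threshold: float = 0.7,
                    a_max: int | None = None, press_tol: float = 0.05
                    ) -> tuple[PLSRModel, SelectionTrace]:
    """Backward elimination on VIP.

    Iteratively drops the single lowest-VIP predictor (alphabetical
    tie-break) until every VIP >= threshold or only two predictors remain.
    Columns named ``<base>_lag<k>`` must additionally improve Q^2 relative
    to the model without them, otherwise they are removed.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float),
                         columns=[f"x{j}" for j in range(np.shape(X)[1])])
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    yv = np.asarray(y, dtype=float).ravel()
    cols = list(map(str, X.columns))
    X = X.set_axis(cols, axis=1)
    steps = []

    # lagged columns enter the model only if they improve Q^2
    lag_decisions = []
    for col in sorted(c for c in cols if LAG_COLUMN_RE.match(c)):
        if len(cols) <= 2:
            break
        without = [c for c in cols if c != col]
        m_with = _fit_with_cv(X[cols], yv, a_max=a_max, press_tol=press_tol)
        m_without = _fit_with_cv(X[without], yv, a_max=a_max, press_tol=press_tol)
        delta = float(m_with.q2[m_with.n_components - 1]
                      - m_without.q2[m_without.n_components - 1])
        retained = delta > 0
        lag_decisions.append((col, delta, retained))
        if not retained:
            cols = without

    while True:
        model = _fit_with_cv(X[cols], yv, a_max=a_max, press_tol=press_tol)
        scores = vip(model)
        order = sorted(range(len(cols)), key=lambda j: (scores[j], cols[j]))
        worst = order[0]
        if len(cols) <= 2 or scores[worst] >= vip_threshold:
            break
        dropped = cols.pop(worst)
        refit = _fit_with_cv(X[cols], yv, a_max=a_max, press_tol=press_tol)
        steps.append((dropped, float(scores[worst]), float(refit.q2[refit.n_components - 1])))

    model = _fit_with_cv(X[cols], yv, a_max=a_max, press_tol=press_tol)
    return model, SelectionTrace(tuple(steps), tuple(cols), tuple(lag_decisions))


def permutation_test(X, y, n_perm: int = 199, seed: int = 0,
                     a_max: int | None = None) -> PermutationResult:
    """Response-permutation validation with Q^2 as the test statistic.

    The predictor set is held fixed; component count is reselected per
    permutation. p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    yv = np.asarray(y, dtype=float).ravel()
    obs = _fit_with_cv(X, yv, a_max=a_max)
    obs_q2 = float(obs.q2[obs.n_components - 1])
    obs_r2y = float(obs.r2y[obs.n_components - 1])
    rng = np.random.default_rng(seed)
    null_q2 = np.empty(n_perm)
    null_r2y = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(yv)
        m = _fit_with_cv(X, yp, a_max=a_max)
        null_q2[b] = m.q2[m.n_components - 1]
        null_r2y[b] = m.r2y[m.n_components - 1]
    p = (1 + int(np.sum(null_q2 >= obs_q2))) / (1 + n_perm)
    return PermutationResult(obs_q2, obs_r2y, null_q2, null_r2y, p, n_perm, seed)


def residual_autocorrelation(model: PLSRModel, X, y, max_lag: int = 5) -> dict:
    """ACF of fit residuals at lags 1..max_lag plus a Ljung-Box test with
    max_lag degrees of freedom. ACF(0)=1 is reported but excluded from Q."""
    yv = np.asarray(y, dtype=float).ravel()
    if yv.size <= max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    resid = yv - model.predict(X)
    acf_vals = _acf(resid, nlags=max_lag, fft=False)
    lb = acorr_ljungbox(resid, lags=[max_lag], return_df=True)
    return {
        "acf": acf_vals,
        "ljung_box_stat": float(lb["lb_stat"].iloc[0]),
        "p_value": float(lb["lb_pvalue"].iloc[0]),
        "max_lag": max_lag,
    }


def collinearity_screen(X: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """All unordered column pairs with |Pearson r| >= threshold."""
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    corr = np.corrcoef(_as_matrix(X), rowvar=False)
    names = list(map(str, X.columns)) if isinstance(X, pd.DataFrame) \
        else [f"x{j}" for j in range(X.shape[1])]
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if abs(r) >= threshold:
                rows.append({"var_a": names[i], "var_b": names[j], "r": float(r)})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])


def model_quality(r2y: float, q2: float) -> str:
    """The published quality gate: good iff R2Y > 0.7 and Q2 > 0.4."""
    return "good" if (r2y > 0.7 and q2 > 0.4) else "poor"
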