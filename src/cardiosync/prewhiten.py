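"""ARIMA prewhitening of uniformly resampled IBI series.

Cross-correlating autocorrelated, nonstationary series produces spurious
correlation; each series is therefore reduced to the residuals of a seasonal
ARIMA model before any cross-correlation is computed.  Model order is chosen
by an exhaustive (non-stepwise) grid search with first differencing fixed
(d = 1; seasonal D = 1 whenever a seasonal period m > 1 is supplied), a
Guerrero-style Box-Cox variance stabilization, and AICc as the selection
criterion (AIC and BIC are reported alongside).

For simulation studies that need tens of thousands of prewhitening fits, a
fast path (``method="ar_diff"``) first-differences the series and fits an
autoregression by least squares with AIC order selection; it removes trend
and autocorrelation equally well for AR-type inputs at a small fraction of
the cost of the state-space grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import boxcox as _boxcox_transform
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .ecg import UniformSeries

__all__ = [
    "ArimaSpec",
    "ArimaFit",
    "boxcox_lambda",
    "fit_auto_arima",
    "prewhiten_series",
    "ljung_box",
]


_WARNED_M1 = False


@dataclass(frozen=True)
class ArimaSpec:
    """Seasonal ARIMA order (p, d, q)(P, D, Q)_m with Box-Cox exponent."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    m: int = 1
    lam: float | None = None  # Box-Cox lambda; None = no transform

    @property
    def n_params(self) -> int:
        return self.p + self.q + self.P + self.Q


@dataclass
class ArimaFit:
    """Result of prewhitening one series."""

    spec: ArimaSpec
    ic: dict
    coefficients: dict
    residuals: UniformSeries
    converged: bool
    ljung_box_p: float = field(default=np.nan)


def boxcox_lambda(series: UniformSeries | np.ndarray, lam_grid: np.ndarray | None = None,
                  n_subseries: int = 10) -> float:
    """Select a Box-Cox exponent by minimizing the coefficient of variation.

    Guerrero-style criterion: the series is split into ``n_subseries``
    contiguous subseries; for a candidate lambda the dispersion measure is
    sd_i / mean_i**(1 - lambda) per subseries, and the lambda (grid over
    [-1, 2]) minimizing the coefficient of variation of that measure across
    subseries is returned.  A constant series returns 1 by convention.

    Raises
    ------
    ValueError
        If any value is non-positive (the power transform is undefined).
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        return 1.0
    if lam_grid is None:
        lam_grid = np.arange(-1.0, 2.0 + 1e-9, 0.05)
    k = max(2, min(n_subseries, len(x) // 8))
    chunks = np.array_split(x, k)
    means = np.array([c.mean() for c in chunks])
    sds = np.array([c.std(ddof=1) for c in chunks])
    best_lam, best_cv = 1.0, np.inf
    for lam in lam_grid:
        disp = sds / means ** (1.0 - lam)
        mu = disp.mean()
        cv = np.inf if mu == 0 else disp.std(ddof=1) / mu
        if cv < best_cv - 1e-12:
            best_cv, best_lam = cv, float(lam)
    return best_lam


def _apply_boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    return _boxcox_transform(x, lam)


def fit_auto_arima(series: UniformSeries, p_max: int = 5, q_max: int = 5,
                   P_max: int = 2, Q_max: int = 2, m: int = 1,
                   use_boxcox: bool = True, min_length: int = 60) -> ArimaFit:
    """Exhaustive seasonal-ARIMA order search; returns the AICc-best residuals.

    The grid covers p <= p_max, q <= q_max with d = 1 fixed; when ``m > 1``
    it also covers P <= P_max, Q <= Q_max with seasonal differencing D = 1.
    With the default ``m = 1`` seasonal terms collapse to none (a warning is
    emitted once) — the seasonal period is a property of the data that the
    caller must supply, not something this routine invents.

    Each candidate is fit by maximum likelihood on the (Box-Cox transformed,
    differenced) series.  Candidates that fail to converge are skipped.  If
    *no* candidate converges, the differenced series itself is returned as
    residuals with ``converged=False``.

    Ties on AICc break toward fewer parameters, then lower q.
    """
    x = series.values
    if len(x) < min_length:
        raise ValueError(f"series length {len(x)} < required {min_length}")
    if np.ptp(x) == 0:
        # degenerate input: nothing to model; flagged fallback
        d_loss = 1 if m <= 1 else 1 + m
        return ArimaFit(spec=ArimaSpec(p=0, d=1, q=0, m=max(m, 1), lam=None),
                        ic={"aicc": np.nan, "aic": np.nan, "bic": np.nan},
                        coefficients={}, converged=False,
                        residuals=UniformSeries(series.rate_hz, np.zeros(len(x) - d_loss),
                                                series.t0_s + d_loss / series.rate_hz))

    lam: float | None = None
    if use_boxcox and np.all(x > 0):
        lam = boxcox_lambda(x)
        xw = _apply_boxcox(x, lam)
    else:
        xw = x.astype(float)
    # rescale to unit variance: extreme lambdas can compress the series by
    # orders of magnitude, which destabilizes the likelihood optimization;
    # only residual correlations are consumed downstream, so scale is free
    sd = xw.std()
    if sd > 0:
        xw = (xw - xw.mean()) / sd

    global _WARNED_M1
    if m <= 1:
        if not _WARNED_M1:
            warnings.warn("seasonal period m=1: seasonal terms and D collapse to none",
                          stacklevel=2)
            _WARNED_M1 = True
        seasonal_grid = [(0, 0, 0, 0)]
        d_loss = 1
    else:
        seasonal_grid = [(P, 1, Q, m) for P, Q in product(range(P_max + 1), range(Q_max + 1))]
        d_loss = 1 + m

    t0_res = series.t0_s + d_loss / series.rate_hz
    candidates: list[tuple[float, int, int, ArimaSpec, object]] = []
    for (p, q), (P, D, Q, mm) in product(product(range(p_max + 1), range(q_max + 1)),
                                         seasonal_grid):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = SARIMAX(xw, order=(p, 1, q),
                                seasonal_order=(P, D, Q, mm) if mm else (0, 0, 0, 0),
                                trend=None, simple_differencing=True)
                res = model.fit(disp=0)
            if not np.isfinite(res.aicc):
                continue
            spec = ArimaSpec(p=p, d=1, q=q, P=P, D=D, Q=Q, m=mm if mm else 1, lam=lam)
            candidates.append((float(res.aicc), spec.n_params, q, spec, res))
        except (ValueError, np.linalg.LinAlgError):
            continue

    if not candidates:
        resid = np.diff(xw)
        if m > 1:
            resid = resid[m:] - resid[:-m]
        spec = ArimaSpec(p=0, d=1, q=0, m=m if m > 1 else 1,
                         D=1 if m > 1 else 0, lam=lam)
        return ArimaFit(spec=spec, ic={"aicc": np.nan, "aic": np.nan, "bic": np.nan},
                        coefficients={}, converged=False,
                        residuals=UniformSeries(series.rate_hz, resid, t0_res))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, spec, res = candidates[0]
    resid = np.asarray(res.resid, dtype=float)
    ic = {"aicc": float(res.aicc), "aic": float(res.aic), "bic": float(res.bic)}
    coefs = dict(zip(res.model.param_names, np.asarray(res.params, float)))
    lb_p = np.nan
    if len(resid) > 21:
        _, lb_p = ljung_box(resid)
    return ArimaFit(spec=spec, ic=ic, coefficients=coefs, converged=True,
                    residuals=UniformSeries(series.rate_hz, resid, t0_res),
                    ljung_box_p=lb_p)


def _ar_ols(dx: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional least-squares AR(p) with intercept; returns (params, resid)."""
    if p == 0:
        mu = dx.mean()
        return np.array([mu]), dx - mu
    y = dx[p:]
    X = np.column_stack([np.ones(len(y))] + [dx[p - k:-k] for k in range(1, p + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def _fit_ar_diff(series: UniformSeries, max_ar: int = 5) -> ArimaFit:
    # first difference removes trend/nonstationarity, then a least-squares
    # autoregression (AIC order selection on a common sample) removes the
    # remaining autocorrelation; direct numpy implementation because this is
    # the inner loop of the surrogate simulations
    dx = np.diff(series.values)
    n_eff = len(dx) - max_ar
    if n_eff < 20:
        raise ValueError("series too short for ar_diff prewhitening")
    best_p, best_aic = 0, np.inf
    for p in range(max_ar + 1):
        # condition on the same max_ar initial values so AICs are comparable
        _, resid = _ar_ols(dx[max_ar - p:], p)
        sigma2 = float(resid @ resid) / n_eff
        aic = n_eff * np.log(max(sigma2, 1e-300)) + 2 * (p + 1)
        if aic < best_aic - 1e-12:
            best_aic, best_p = aic, p
    beta, resid = _ar_ols(dx, best_p)
    coefs = {"const": float(beta[0]),
             **{f"ar.L{k}": float(b) for k, b in enumerate(beta[1:], 1)}}
    t0_res = series.t0_s + (1 + best_p) / series.rate_hz
    spec = ArimaSpec(p=best_p, d=1, q=0, lam=None)
    return ArimaFit(spec=spec, ic={"aicc": np.nan, "aic": float(best_aic), "bic": np.nan},
                    coefficients=coefs, converged=True,
                    residuals=UniformSeries(series.rate_hz, resid, t0_res))


def prewhiten_series(series: UniformSeries, method: str = "auto_arima",
                     **kwargs) -> ArimaFit:
    """Prewhiten one uniform series.

    ``method="auto_arima"`` runs the exhaustive grid search
    (:func:`fit_auto_arima`); ``method="ar_diff"`` runs the fast
    difference-plus-autoregression path used for large simulation studies.
    """
    if method == "auto_arima":
        return fit_auto_arima(series, **kwargs)
    if method == "ar_diff":
        return _fit_ar_diff(series, **kwargs)
    raise ValueError(f"unknown prewhitening method {method!r}")


def ljung_box(series: UniformSeries | np.ndarray, n_lags: int = 20) -> tuple[float, float]:
    """Ljung-Box portmanteau test for residual whiteness.

    Returns ``(statistic, p_value)`` with the p-value from a chi-square with
    ``n_lags`` degrees of freedom.
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    if len(x) <= n_lags + 1:
        raise ValueError(f"series length {len(x)} too short for {n_lags} lags")
    tbl = acorr_ljungbox(x, lags=[n_lags], return_df=True)
    return float(tbl["lb_stat"].iloc[0]), float(tbl["lb_pvalue"].iloc[0])
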