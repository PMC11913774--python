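"""Lagged cross-correlation synchrony between two prewhitened IBI series.

The synchrony index for one dyad-block is the arithmetic mean of the
cross-correlation function over lags -L..+L (L = 12 samples = 3 s at 4 Hz,
25 values in total), Fisher-Z transformed, and multiplied by 100 for
reporting.  The sign is kept: positive values indicate in-phase, negative
values antiphase co-fluctuation.

Orientation convention: subject 2's series is slid over subject 1's
reference, so a positive lag means subject 1 leads subject 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import IbiSeries, UniformSeries, resample_ibi
from .prewhiten import ArimaFit, prewhiten_series

__all__ = [
    "CcfResult",
    "SynchronyConfig",
    "SynchronyValue",
    "cross_correlation",
    "lag_group_means",
    "average_ccf",
    "fisher_z",
    "dyad_block_synchrony",
    "align_series",
]

#: lag-group partition of the 25 lags (8 + 9 + 8)
LAG_GROUPS = {"negative": (-12, -5), "zero": (-4, 4), "positive": (5, 12)}


@dataclass
class CcfResult:
    """Cross-correlation function over symmetric lags.

    ``values[k]`` is the Pearson correlation between series 1 at time t and
    series 2 at time t + lags[k]; positive lags mean subject 1 leads.
    """

    lags: np.ndarray
    values: np.ndarray
    orientation: str = "s2 slid over s1"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise ValueError("lags and values must have equal length")

    @property
    def lag_group_means(self) -> dict:
        return lag_group_means(self)

    @property
    def average_ccf(self) -> float:
        return average_ccf(self)

    @property
    def fisher_z(self) -> float:
        return fisher_z(self.average_ccf)

    @property
    def scaled(self) -> float:
        """Fisher-Z synchrony x 100 (reporting convention)."""
        return 100.0 * self.fisher_z


@dataclass
class SynchronyConfig:
    """Configuration of the per-block synchrony pipeline."""

    rate_hz: float = 4.0
    max_lag: int = 12
    prewhiten_method: str = "auto_arima"
    prewhiten_kwargs: dict = field(default_factory=dict)


@dataclass
class SynchronyValue:
    """End-to-end synchrony for one dyad-block, with diagnostics."""

    average_ccf: float
    fisher_z: float
    scaled: float
    ccf: CcfResult
    fit1: ArimaFit
    fit2: ArimaFit

    @property
    def converged(self) -> bool:
        return self.fit1.converged and self.fit2.converged


def align_series(a: UniformSeries, b: UniformSeries) -> tuple[np.ndarray, np.ndarray]:
    """Trim two uniform series (equal rate) to their overlapping time span.

    Grids are aligned by the series' start times; a sub-sample offset below
    half a sample is tolerated and resolved by rounding.
    """
    if a.rate_hz != b.rate_hz:
        raise ValueError("series rates differ")
    dt = 1.0 / a.rate_hz
    # integer sample offset of b's grid relative to a's
    off = (b.t0_s - a.t0_s) / dt
    k = int(round(off))
    if abs(off - k) > 0.5:
        raise ValueError("series grids are not alignable")
    if k >= 0:
        xa, xb = a.values[k:], b.values
    else:
        xa, xb = a.values, b.values[-k:]
    n = min(len(xa), len(xb))
    return xa[:n], xb[:n]


def cross_correlation(res1: UniformSeries, res2: UniformSeries,
                      max_lag: int = 12) -> CcfResult:
    """Lagged Pearson cross-correlation with full-series normalization.

    The value at lag k uses the full-series means and (biased) standard
    deviations, so estimates remain bounded and stable at the maximum lag:

        r(k) = sum_t (x_t - xbar)(y_{t+k} - ybar) / (n * sx * sy)

    Positive k: subject 2's series shifted *earlier*, i.e. subject 1 leads.
    """
    x, y = align_series(res1, res2)
    n = len(x)
    if n < 10 * max_lag:
        raise ValueError(f"overlap {n} samples < required {10 * max_lag}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            num = np.dot(xc[:n - k], yc[k:])
        else:
            num = np.dot(xc[-k:], yc[:n + k])
        vals[i] = num / (n * sx * sy)
    return CcfResult(lags=lags, values=vals)


def lag_group_means(ccf: CcfResult) -> dict:
    """Mean CCF per lag group: negative (-12..-5), zero (-4..4), positive (5..12)."""
    if len(ccf.lags) != 25:
        raise ValueError(f"lag-group partition is defined for 25 lags, got {len(ccf.lags)}")
    out = {}
    for name, (lo, hi) in LAG_GROUPS.items():
        sel = (ccf.lags >= lo) & (ccf.lags <= hi)
        out[name] = float(ccf.values[sel].mean())
    return out


def average_ccf(ccf: CcfResult) -> float:
    """Signed arithmetic mean of all CCF values across lags — the per-block
    synchrony index before Fisher transformation."""
    return float(ccf.values.mean())


def fisher_z(r: float) -> float:
    """Fisher's Z (atanh) variance-stabilizing transform of a correlation."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def dyad_block_synchrony(ibi1: IbiSeries, ibi2: IbiSeries,
                         cfg: SynchronyConfig | None = None) -> SynchronyValue:
    """Full per-block pipeline: resample both cleaned IBI series to a uniform
    grid, prewhiten each with ARIMA, cross-correlate the residuals, average
    over lags, and Fisher-Z transform."""
    cfg = cfg or SynchronyConfig()
    u1 = resample_ibi(ibi1, rate_hz=cfg.rate_hz)
    u2 = resample_ibi(ibi2, rate_hz=cfg.rate_hz)
    fit1 = prewhiten_series(u1, method=cfg.prewhiten_method, **cfg.prewhiten_kwargs)
    fit2 = prewhiten_series(u2, method=cfg.prewhiten_method, **cfg.prewhiten_kwargs)
    ccf = cross_correlation(fit1.residuals, fit2.residuals, max_lag=cfg.max_lag)
    avg = average_ccf(ccf)
    z = fisher_z(avg)
    return SynchronyValue(average_ccf=avg, fisher_z=z, scaled=100.0 * z,
                          ccf=ccf, fit1=fit1, fit2=fit2)
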