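"""Cross-correlation of hormone and isotope series; lag-to-months conversion.

Along a plate, larger positions are older growth.  A hormone event that
happens earlier in the year than the isotope crest of the same cycle sits at
a larger position, so with the convention CCF(k) = corr(T_{i+k}, N_i) the
best lag k is positive exactly when T precedes the isotope signal in time.
Assuming both cycles are annual, a lag of k samples converts to months as

    offset = |k| * spacing_cm / T_period_cm * 12.

The hormone period (not the isotope period) is used in the conversion; the
resolution of the offset is therefore one sample, i.e. spacing/period * 12
months (~1.1-1.7 months at 2-cm spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseResult",
    "cross_correlation",
    "offset_months",
    "estimate_phase",
]


@dataclass(frozen=True)
class PhaseResult:
    lag_samples: int
    lag_cm: float
    max_ccf: float
    t_precedes_n: bool
    offset_months: float
    significance_bound: float  # 1.96 / sqrt(n)
    significant: bool


def cross_correlation(
    x: np.ndarray, y: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample CCF(k) = corr(x_{i+k}, y_i) for k = -max_lag..max_lag.

    Time-series convention: covariances at each lag are summed over the
    overlap and divided by n (biased), means and the normalizing variances
    are taken over the full series, which keeps |ccf| <= 1 by
    Cauchy-Schwarz.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("series must have equal length")
    if n < 10:
        raise ValueError("need at least 10 samples")
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < n/2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance series has no cross-correlation")
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            ccf[i] = np.sum(xc[k:] * yc[: n - k]) / n
        else:
            ccf[i] = np.sum(xc[: n + k] * yc[-k:]) / n
    return lags, ccf / (sx * sy)


def offset_months(lag_samples: int, spacing_cm: float, t_period_cm: float) -> float:
    """Months of offset implied by a lag, treating one T period as 12 months."""
    if t_period_cm <= 0:
        raise ValueError("t_period_cm must be > 0")
    return abs(lag_samples) * spacing_cm / t_period_cm * 12.0


def estimate_phase(
    t_series: np.ndarray,
    n_series: np.ndarray,
    spacing_cm: float,
    t_period_cm: float,
    n_period_cm: float,
) -> PhaseResult:
    """Best-lag phase offset of (detrended) T relative to the isotope series.

    The lag search is limited to half the isotope period so the match cannot
    lock onto the adjacent cycle.  A best correlation below the 1.96/sqrt(n)
    bound flags the result non-significant (it is still returned).
    Ties resolve toward the smallest |lag|, then the negative one.
    """
    if t_period_cm <= 0 or n_period_cm <= 0:
        raise ValueError("periods must be > 0")
    max_lag = max(1, int(np.floor((n_period_cm / 2.0) / spacing_cm)))
    lags, ccf = cross_correlation(t_series, n_series, max_lag)
    order = np.lexsort((lags > 0, np.abs(lags), -ccf))
    k = int(lags[order[0]])
    best = float(ccf[order[0]])
    n = len(np.asarray(t_series))
    bound = 1.96 / np.sqrt(n)
    return PhaseResult(
        lag_samples=k,
        lag_cm=k * spacing_cm,
        max_ccf=best,
        t_precedes_n=k > 0,
        offset_months=offset_months(k, spacing_cm, t_period_cm),
        significance_bound=bound,
        significant=abs(best) >= bound,
    )
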