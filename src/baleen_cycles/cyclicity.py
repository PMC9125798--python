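"""Autocorrelation diagnostics and AR-spectral period estimation.

The dominant cycle length of a detrended hormone profile is estimated the
classic parametric way: fit autoregressive models AR(p) for p = 0..max_order
by Yule-Walker / Levinson-Durbin, choose p minimizing AIC(p) = n*ln(s2_p) +
2p, evaluate the model-implied spectral density

    S(f) = s2 / |1 - sum_j a_j exp(-i 2 pi f j)|^2

on a dense frequency grid (cycles per sample), and convert the spectral peak
frequency to a period in cm via period = spacing / f.  The peak search is
restricted to a configurable period band (default 4-60 cm) so that neither
residual trend nor sub-seasonal noise can capture the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocess import DetrendConfig, detrend
from .profile_io import AnalysisWindow, HormoneProfile

__all__ = [
    "AcfResult",
    "SpectralResult",
    "SpectralConfig",
    "NoDominantCycleError",
    "autocorrelation",
    "autocovariance",
    "levinson_durbin",
    "fit_ar_aic",
    "ar_spectrum",
    "estimate_series_period",
    "estimate_period",
]


class NoDominantCycleError(RuntimeError):
    """The AR spectrum has no local maximum inside the period search band."""


@dataclass(frozen=True)
class AcfResult:
    lags: np.ndarray
    acf: np.ndarray
    significance_bound: float  # 1.96 / sqrt(n)
    n: int


@dataclass(frozen=True)
class SpectralConfig:
    max_order: Optional[int] = None  # default min(n // 3, 40)
    grid_points: int = 4096
    period_band_cm: tuple[float, float] = (4.0, 60.0)


@dataclass(frozen=True)
class SpectralResult:
    ar_order: int
    ar_coefficients: np.ndarray
    innovation_variance: float
    peak_frequency: float  # cycles per sample
    period_cm: float  # = spacing_cm / peak_frequency
    frequencies: np.ndarray
    spectrum: np.ndarray
    sigma_cm: float  # detrend filter width used
    spacing_cm: float


def autocovariance(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/n) mean-removed sample autocovariances, lags 0..max_lag."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be < series length")
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[n - 1 :]
    return full[: max_lag + 1] / n


def autocorrelation(series: np.ndarray, max_lag: int) -> AcfResult:
    """Sample ACF with the usual 1.96/sqrt(n) white-noise significance bound."""
    acov = autocovariance(series, max_lag)
    if acov[0] <= 0:
        raise ValueError("zero-variance series has no autocorrelation")
    n = len(np.asarray(series))
    return AcfResult(
        lags=np.arange(max_lag + 1),
        acf=acov / acov[0],
        significance_bound=1.96 / np.sqrt(n),
        n=n,
    )


def levinson_durbin(acov: np.ndarray, order: int):
    """Solve the Yule-Walker equations recursively.

    Returns (coefficients a_1..a_p per order, innovation variance per order):
    lists indexed by p = 0..order.  The innovation variance is non-increasing
    in p; the recursion stops early (truncating the candidate orders) if it
    hits zero, which only happens for deterministic inputs.
    """
    acov = np.asarray(acov, dtype=float)
    if acov[0] <= 0:
        raise ValueError("zero-variance input")
    coeffs: list[np.ndarray] = [np.array([])]
    sigma2 = [float(acov[0])]
    a = np.zeros(0)
    err = float(acov[0])
    for p in range(1, order + 1):
        if err <= 0:
            break
        k = (acov[p] - np.dot(a, acov[p - 1 : 0 : -1])) / err
        a_new = np.concatenate([a - k * a[::-1], [k]]) if p > 1 else np.array([k])
        err = err * (1.0 - k * k)
        a = a_new
        coeffs.append(a.copy())
        sigma2.append(max(err, 0.0))
    return coeffs, sigma2


def fit_ar_aic(
    series: np.ndarray, max_order: Optional[int] = None
) -> tuple[int, np.ndarray, float]:
    """Select the AR order minimizing AIC(p) = n*ln(s2_p) + 2p.

    Ties and the zero-variance floor resolve toward the smallest order.
    Returns (order, coefficients a_1..a_p, innovation variance).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples to fit AR models")
    if max_order is None:
        max_order = min(n // 3, 40)
    if max_order >= n / 2:
        raise ValueError("max_order must be < n/2")
    acov = autocovariance(x, max_order)
    if acov[0] <= 0:
        raise ValueError("zero-variance series")
    coeffs, sigma2 = levinson_durbin(acov, max_order)
    floor = acov[0] * 1e-14  # guard: ln of an exactly-deterministic fit
    aic = np.array(
        [n * np.log(max(s, floor)) + 2.0 * p for p, s in enumerate(sigma2)]
    )
    p_best = int(np.argmin(aic))  # argmin takes the first (smallest p) on ties
    return p_best, coeffs[p_best], sigma2[p_best]


def ar_spectrum(
    coefficients: np.ndarray, sigma2: float, frequencies: np.ndarray
) -> np.ndarray:
    """AR model spectral density on a grid of frequencies in (0, 0.5]."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("frequencies must lie in (0, 0.5]")
    a = np.asarray(coefficients, dtype=float)
    if len(a) == 0:
        return np.full_like(f, float(sigma2))
    j = np.arange(1, len(a) + 1)
    transfer = 1.0 - np.exp(-2.0j * np.pi * f[:, None] * j[None, :]).dot(a)
    return float(sigma2) / np.abs(transfer) ** 2


def estimate_series_period(
    series: np.ndarray,
    spacing_cm: float,
    detrend_config: DetrendConfig = DetrendConfig(),
    spectral_config: SpectralConfig = SpectralConfig(),
    label: str = "series",
) -> SpectralResult:
    """Detrend, AR-fit, and read the dominant period off the AR spectrum.

    The spectral peak must be a genuine local maximum of the density whose
    period falls inside ``period_band_cm``; among several local maxima the
    highest density wins, with ties broken toward lower frequency.
    """
    resid = detrend(series, spacing_cm, detrend_config)
    order, coefs, sigma2 = fit_ar_aic(resid, spectral_config.max_order)

    freqs = np.linspace(0.0, 0.5, spectral_config.grid_points + 1)[1:]
    dens = ar_spectrum(coefs, sigma2, freqs)

    lo_cm, hi_cm = spectral_config.period_band_cm
    in_band = (freqs >= spacing_cm / hi_cm) & (freqs <= spacing_cm / lo_cm)
    interior = np.zeros_like(freqs, dtype=bool)
    interior[1:-1] = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    candidates = np.flatnonzero(interior & in_band)
    if len(candidates) == 0:
        raise NoDominantCycleError(
            f"{label}: no spectral local maximum with period in "
            f"[{lo_cm}, {hi_cm}] cm (AR order {order})"
        )
    best = candidates[np.argmax(dens[candidates])]
    # ties toward lower frequency
    tied = candidates[dens[candidates] == dens[best]]
    best = int(tied.min())
    f_peak = float(freqs[best])
    return SpectralResult(
        ar_order=order,
        ar_coefficients=coefs,
        innovation_variance=sigma2,
        peak_frequency=f_peak,
        period_cm=spacing_cm / f_peak,
        frequencies=freqs,
        spectrum=dens,
        sigma_cm=detrend_config.sigma_cm,
        spacing_cm=spacing_cm,
    )


def estimate_period(
    profile: HormoneProfile,
    detrend_config: DetrendConfig = DetrendConfig(),
    spectral_config: SpectralConfig = SpectralConfig(),
    window: Optional[AnalysisWindow] = None,
) -> SpectralResult:
    """Dominant T-cycle period of a (optionally windowed) profile."""
    if window is not None:
        profile = profile.window(window)
    return estimate_series_period(
        profile.testosterone,
        profile.spacing_cm,
        detrend_config,
        spectral_config,
        label=f"whale {profile.whale_id}",
    )
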