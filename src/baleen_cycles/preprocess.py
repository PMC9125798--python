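"""Gaussian low-pass detrending of plate profiles.

Slow drift along a plate (multi-year trends in hormone deposition or
extraction efficiency) would dominate an AR spectrum at low frequency, so
profiles are detrended before spectral analysis by subtracting a Gaussian
low-pass smooth.  For a sinusoid of period P cm the smooth retains the
fraction exp(-2*pi^2*sigma^2/P^2) of the amplitude, so with the default
sigma = 8 cm the annual band (~14-22 cm) passes almost untouched into the
residual (99.3% retained at 16 cm, 92.6% at 22 cm) while variation slower
than 60 cm is largely absorbed into the trend (>= 70% at 60 cm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["DetrendConfig", "gaussian_smooth", "detrend", "gaussian_transfer"]


@dataclass(frozen=True)
class DetrendConfig:
    """Filter width in cm; boundaries handled by reflection; kernel cut at
    ``truncation`` standard deviations."""

    sigma_cm: float = 8.0
    boundary_rule: str = "reflect"
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_cm <= 0:
            raise ValueError("sigma_cm must be > 0")
        if self.boundary_rule != "reflect":
            raise ValueError("only 'reflect' boundary handling is supported")


def gaussian_transfer(period_cm: float, sigma_cm: float) -> float:
    """Amplitude fraction a sinusoid of the given period keeps after the
    Gaussian smooth (continuous-kernel closed form)."""
    return float(np.exp(-2.0 * np.pi**2 * sigma_cm**2 / period_cm**2))


def gaussian_smooth(
    series: np.ndarray, spacing_cm: float, config: DetrendConfig = DetrendConfig()
) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel (sigma given in cm)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    if config.sigma_cm <= spacing_cm:
        raise ValueError("sigma_cm must exceed the sample spacing")
    return gaussian_filter1d(
        series,
        sigma=config.sigma_cm / spacing_cm,
        mode="reflect",
        truncate=config.truncation,
    )


def detrend(
    series: np.ndarray, spacing_cm: float, config: DetrendConfig = DetrendConfig()
) -> np.ndarray:
    """High-pass residual: the series minus its Gaussian smooth."""
    series = np.asarray(series, dtype=float)
    return series - gaussian_smooth(series, spacing_cm, config)
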