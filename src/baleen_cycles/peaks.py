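"""Peak detection, cycle segmentation, plate summaries, and cycle ages.

A "T peak" is a single sample strictly higher than its four neighbours (two
prior, two subsequent).  Strict inequality means plateaus of tied values
never yield a peak, and the first/last two samples of a plate can never be
peaks.  Consecutive peaks bound one complete cycle; each complete cycle has
one minimum, the baseline is the mean of those minima (partial cycles at the
plate ends contribute nothing), and per-cycle ages are back-calculated by
subtracting the cycle count from the whale's estimated terminal age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .profile_io import HormoneProfile

__all__ = [
    "PeakSet",
    "CycleSet",
    "PlateSummary",
    "detect_peaks",
    "estimate_noise_sd",
    "segment_cycles",
    "assign_cycle_ages",
    "summarize_plate",
]


@dataclass(frozen=True)
class PeakSet:
    indices: np.ndarray
    positions_cm: np.ndarray
    heights: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class CycleSet:
    """Complete cycles between consecutive peaks, ordered along the plate
    (recent end first, matching index order)."""

    left_peak_indices: np.ndarray  # lower-index (more recent) bounding peak
    right_peak_indices: np.ndarray
    min_values: np.ndarray
    min_indices: np.ndarray
    periods_cm: np.ndarray  # peak-to-peak distance
    ratios: np.ndarray  # leading (lower-index) peak height / cycle minimum
    baseline: Optional[float]  # mean of cycle minima; None if no complete cycle
    ages_yr: Optional[np.ndarray] = None  # assigned later; recent cycle = oldest age

    @property
    def n_cycles(self) -> int:
        return len(self.periods_cm)


@dataclass(frozen=True)
class PlateSummary:
    whale_id: str
    n_peaks: int
    mean_peak: Optional[float]
    sd_peak: Optional[float]
    baseline: Optional[float]
    mean_ratio: Optional[float]
    sd_ratio: Optional[float]
    max_t: float
    min_t: float
    mean_t: float
    median_t: float
    cv_peaks_pct: Optional[float]  # 100 * sd(peaks) / mean(peaks), n-1 sd
    mean_cycle_period_cm: Optional[float]


def estimate_noise_sd(series: np.ndarray) -> float:
    """Robust sample-to-sample noise scale from first differences.

    Uses the 25th percentile of |dx| (for white Gaussian noise
    P25|dx| = sqrt(2) * 0.3186 * sigma): on a pulse train the large
    pulse-edge differences contaminate well over half of all differences,
    so a low quantile of the flat-baseline differences is used rather than
    the median."""
    d = np.abs(np.diff(np.asarray(series, dtype=float)))
    return float(np.percentile(d, 25) / (np.sqrt(2.0) * 0.31864))


def detect_peaks(
    series: np.ndarray,
    spacing_cm: float = 2.0,
    positions_cm: Optional[np.ndarray] = None,
    min_prominence: Optional[float] = None,
) -> PeakSet:
    """All and only samples strictly greater than both 2-neighbourhoods.

    ``positions_cm`` overrides the default 0-based position axis, e.g. for a
    windowed profile whose first sample is not at 0 cm.  ``min_prominence``
    (same units as the series) optionally discards low-prominence local
    maxima that the strict rule picks out of noise; the default (None) is
    the pure 4-neighbour rule.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 samples for the 4-neighbour rule")
    core = x[2 : n - 2]
    is_peak = (
        (core > x[0 : n - 4])
        & (core > x[1 : n - 3])
        & (core > x[3 : n - 1])
        & (core > x[4:n])
    )
    idx = np.flatnonzero(is_peak) + 2
    if min_prominence is not None and len(idx):
        from scipy.signal import peak_prominences

        prom = peak_prominences(x, idx)[0]
        idx = idx[prom >= min_prominence]
    pos = (
        np.asarray(positions_cm, dtype=float)[idx]
        if positions_cm is not None
        else idx * spacing_cm
    )
    return PeakSet(indices=idx, positions_cm=pos, heights=x[idx])


def _cycle_minimum(x: np.ndarray, left: int, right: int) -> int:
    """Index of the smallest value strictly between two peaks; ties resolve
    to the index closest to the midpoint, then the earlier one."""
    interior = np.arange(left + 1, right)
    vals = x[interior]
    m = vals.min()
    tied = interior[vals == m]
    mid = (left + right) / 2.0
    dist = np.abs(tied - mid)
    return int(tied[np.lexsort((tied, dist))[0]])


def segment_cycles(
    series: np.ndarray, peaks: PeakSet, spacing_cm: float
) -> CycleSet:
    """One cycle per consecutive peak pair; empty (baseline None) with < 2
    peaks."""
    x = np.asarray(series, dtype=float)
    if len(peaks) < 2:
        empty = np.array([], dtype=int)
        return CycleSet(
            left_peak_indices=empty,
            right_peak_indices=empty,
            min_values=np.array([]),
            min_indices=empty,
            periods_cm=np.array([]),
            ratios=np.array([]),
            baseline=None,
        )
    lefts = peaks.indices[:-1]
    rights = peaks.indices[1:]
    min_idx = np.array([_cycle_minimum(x, l, r) for l, r in zip(lefts, rights)])
    min_val = x[min_idx]
    periods = (rights - lefts) * spacing_cm
    # a zero minimum makes the peak/minimum ratio undefined, not infinite
    with np.errstate(divide="ignore"):
        ratios = np.where(min_val > 0, x[lefts] / min_val, np.nan)
    return CycleSet(
        left_peak_indices=lefts,
        right_peak_indices=rights,
        min_values=min_val,
        min_indices=min_idx,
        periods_cm=periods.astype(float),
        ratios=ratios,
        baseline=float(np.mean(min_val)),
    )


def assign_cycle_ages(n_cycles: int, terminal_age_yr: float) -> np.ndarray:
    """Ages of cycles ordered oldest first: terminal - n, ..., terminal - 1.

    The whale's estimated age at death anchors the chronology; each cycle is
    one year, so the oldest documented cycle occurred at terminal - n years.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if terminal_age_yr <= n_cycles:
        raise ValueError(
            f"terminal age {terminal_age_yr} inconsistent with {n_cycles} cycles"
        )
    return terminal_age_yr - n_cycles + np.arange(n_cycles, dtype=float)


def _sd(values: np.ndarray) -> Optional[float]:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else None


def summarize_plate(
    profile: HormoneProfile, peaks: PeakSet, cycles: CycleSet
) -> PlateSummary:
    """Whole-plate summary: sample stats over every sample, peak stats over
    detected peaks, baseline/ratio/period stats over complete cycles."""
    t = profile.testosterone
    n_peaks = len(peaks)
    mean_peak = float(np.mean(peaks.heights)) if n_peaks else None
    sd_peak = _sd(peaks.heights) if n_peaks else None
    cv = (
        100.0 * sd_peak / mean_peak
        if (sd_peak is not None and mean_peak and mean_peak > 0)
        else None
    )
    finite_ratios = cycles.ratios[np.isfinite(cycles.ratios)]
    return PlateSummary(
        whale_id=profile.whale_id,
        n_peaks=n_peaks,
        mean_peak=mean_peak,
        sd_peak=sd_peak,
        baseline=cycles.baseline,
        mean_ratio=float(np.mean(finite_ratios)) if len(finite_ratios) else None,
        sd_ratio=_sd(finite_ratios) if len(finite_ratios) else None,
        max_t=float(np.max(t)),
        min_t=float(np.min(t)),
        mean_t=float(np.mean(t)),
        median_t=float(np.median(t)),
        cv_peaks_pct=cv,
        mean_cycle_period_cm=(
            float(np.mean(cycles.periods_cm)) if cycles.n_cycles else None
        ),
    )
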