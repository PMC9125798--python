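"""Published nine-whale bowhead reference values.

The raw per-position hormone and isotope series of the nine-male bowhead
baleen study were not deposited, but its printed per-whale values are usable
directly as inputs: collection metadata and candidate ages, and the
per-plate cycle summary (peak counts, hormone and isotope cycle periods,
phase offsets, peak/baseline statistics).  These tables drive worked
examples, consistency tests, and the reproduction of the study's
cross-whale correlation and phase arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profile_io import WhaleMetadata

__all__ = [
    "COMPARATOR_AGES_YR",
    "whale_metadata",
    "whale_metadata_records",
    "cycle_summary",
]

#: AAR ages of the four known males in the same body-length class as the
#: largest whale, whose length exceeds every growth-curve asymptote
COMPARATOR_AGES_YR = (135.0, 146.0, 159.0, 172.0)

# one row per whale: numbered in order of best-available age
_METADATA_ROWS = [
    # id, length m, month, year, aar age, length age, gumline cut
    ("W1", 10.51, 9, 2008, 14.0, 10.0, False),
    ("W2", 13.43, 8, 2008, 18.0, 29.0, False),
    ("W3", 12.75, 7, 1998, 21.0, 22.0, False),
    ("W4", 12.80, 8, 2010, None, 23.0, False),
    ("W5", 11.65, 8, 2000, 24.0, 15.0, True),
    ("W6", 14.10, 4, 2009, 44.0, 41.0, True),
    ("W7", 14.33, 8, 2011, None, 48.0, False),
    ("W8", 14.88, 8, 2008, 115.0, 78.0, False),
    # the largest male exceeds every growth-curve maximum; his length-based
    # age is the comparator average of COMPARATOR_AGES_YR
    ("W9", 15.77, 9, 2009, None, 153.0, False),
]

_SUMMARY_COLUMNS = [
    "whale_id",
    "est_age_yr",
    "n_peaks",
    "t_period_cm",
    "n_period_cm",
    "phase_months",
    "mean_peak",
    "sd_peak",
    "baseline",
    "sd_baseline",
    "mean_ratio",
    "sd_ratio",
    "max_t",
    "min_t",
    "mean_t",
    "median_t",
]

_SUMMARY_ROWS = [
    ("W1", 14, 5, 18.35, 15.50, 0.00, 3.06, 1.03, 0.90, 0.29, 4.04, 2.95, 4.87, 0.53, 1.64, 1.52),
    ("W2", 18, 11, 19.23, 20.80, 2.50, 2.78, 0.66, 0.73, 0.25, 3.71, 1.37, 3.73, 0.28, 1.65, 1.49),
    ("W3", 21, 12, 21.51, 20.60, 3.35, 11.77, 2.00, 1.22, 0.28, 9.70, 3.54, 15.67, 0.80, 5.19, 4.70),
    ("W4", 23, 12, 16.95, 17.50, 2.83, 7.19, 1.50, 1.22, 0.47, 6.29, 1.74, 9.89, 0.62, 3.80, 3.14),
    ("W5", 24, 15, 17.54, 17.90, 2.74, 3.99, 0.72, 0.81, 0.19, 5.00, 1.35, 5.53, 0.46, 2.23, 1.91),
    ("W6", 44, 13, 16.53, 17.20, 2.90, 8.10, 1.59, 1.36, 0.51, 6.85, 3.40, 11.05, 0.51, 4.39, 4.05),
    ("W7", 48, 16, 16.13, 17.10, 2.98, 4.26, 1.22, 0.72, 0.36, 7.79, 5.82, 5.65, 0.18, 2.21, 1.76),
    ("W8", 115, 20, 14.49, 14.60, 3.31, 9.10, 3.05, 2.24, 0.32, 4.12, 1.47, 14.70, 1.79, 5.37, 4.65),
    ("W9", 153, 22, 14.49, 14.90, 1.66, 10.96, 4.53, 2.83, 0.84, 4.49, 2.77, 21.56, 1.72, 6.61, 5.82),
]


def whale_metadata() -> pd.DataFrame:
    """Collection metadata and candidate ages, one row per whale."""
    return pd.DataFrame(
        _METADATA_ROWS,
        columns=[
            "whale_id",
            "body_length_m",
            "collection_month",
            "collection_year",
            "aar_age_yr",
            "length_age_yr",
            "gumline_cut",
        ],
    )


def whale_metadata_records() -> list[WhaleMetadata]:
    """The same metadata as validated :class:`WhaleMetadata` records."""
    return [
        WhaleMetadata(
            whale_id=wid,
            body_length_m=length,
            collection_month=month,
            collection_year=year,
            aar_age_yr=aar,
            length_age_yr=la,
            gumline_cut=cut,
        )
        for wid, length, month, year, aar, la, cut in _METADATA_ROWS
    ]


def cycle_summary() -> pd.DataFrame:
    """Per-whale cycle metrics: periods (cm), phase offsets (months), peak,
    baseline and whole-plate T statistics (ng/g)."""
    df = pd.DataFrame(_SUMMARY_ROWS, columns=_SUMMARY_COLUMNS)
    df["cv_peaks_pct"] = 100.0 * df["sd_peak"] / df["mean_peak"]
    return df
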