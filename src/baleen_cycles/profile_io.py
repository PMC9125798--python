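"""Data model and tidy-table I/O for baleen hormone profiles.

A baleen plate grows continuously from the gum while wearing at the tip, so a
single plate read from the most recently grown end (position 0 cm) toward the
tip (increasing position) is a retrospective time series: larger positions are
older growth.  Profiles hold immunoreactive testosterone (T, ng per g baleen
powder) drilled at a uniform spacing (2 cm by default) and, when available,
the stable-nitrogen-isotope series (delta-15-N, permil) measured at the same
positions, which supplies the annual time anchor.

Tables are tidy long-format CSV (UTF-8, "." decimal): one row per
(whale, position) for profiles, one row per whale for metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "HormoneProfile",
    "WhaleMetadata",
    "AnalysisWindow",
    "read_profiles",
    "write_profiles",
    "read_metadata",
    "write_metadata",
]

#: default drill spacing along the plate, cm
DEFAULT_SPACING_CM = 2.0
#: absolute tolerance on spacing uniformity, cm
SPACING_TOL = 1e-9
#: the 4-neighbour peak rule can never fire with fewer samples than this
MIN_SAMPLES = 5

PROFILE_COLUMNS = ["whale_id", "position_cm", "testosterone_ng_g", "d15n_permil"]
METADATA_COLUMNS = [
    "whale_id",
    "body_length_m",
    "collection_month",
    "collection_year",
    "aar_age_yr",
    "length_age_yr",
    "age_override_yr",
    "gumline_cut",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A table or profile violates an invariant of the data model."""


@dataclass(frozen=True)
class HormoneProfile:
    """One whale's co-registered hormone (and optional isotope) series.

    Parameters
    ----------
    whale_id
        Identifier of the whale/plate.
    positions
        Sampling positions in cm, 0 = most recently grown baleen, strictly
        increasing toward the tip (older growth) with uniform spacing.
    testosterone
        Immunoreactive T in ng per g baleen powder, aligned with positions.
    d15n
        Optional delta-15-N in permil on the same grid; ``None`` when the
        isotope series was not measured for this whale.
    gumline_cut
        True when the plate was cut at the gumline and lacks the embedded
        root (roughly one year of the most recent growth).  Metadata only:
        it affects interpretation of position 0, not any computation.
    """

    whale_id: str
    positions: np.ndarray
    testosterone: np.ndarray
    d15n: Optional[np.ndarray] = None
    gumline_cut: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        t = np.asarray(self.testosterone, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "testosterone", t)
        if self.d15n is not None:
            n = np.asarray(self.d15n, dtype=float)
            object.__setattr__(self, "d15n", n)
        if pos.ndim != 1 or t.ndim != 1:
            raise ValidationError(f"whale {self.whale_id}: series must be 1-D")
        if len(pos) != len(t):
            raise ValidationError(
                f"whale {self.whale_id}: positions ({len(pos)}) and testosterone "
                f"({len(t)}) lengths differ"
            )
        if self.d15n is not None and len(self.d15n) != len(pos):
            raise ValidationError(
                f"whale {self.whale_id}: d15n length {len(self.d15n)} != {len(pos)}"
            )
        if len(pos) < MIN_SAMPLES:
            raise ValidationError(
                f"whale {self.whale_id}: at least {MIN_SAMPLES} samples required, "
                f"got {len(pos)}"
            )
        steps = np.diff(pos)
        if np.any(steps <= 0):
            i = int(np.argmax(steps <= 0))
            raise ValidationError(
                f"whale {self.whale_id}: positions not strictly increasing at "
                f"position {pos[i + 1]:g} cm"
            )
        if np.any(np.abs(steps - steps[0]) > SPACING_TOL):
            i = int(np.argmax(np.abs(steps - steps[0]) > SPACING_TOL))
            raise ValidationError(
                f"whale {self.whale_id}: non-uniform spacing at position "
                f"{pos[i + 1]:g} cm (step {steps[i]:g}, expected {steps[0]:g})"
            )
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValidationError(
                f"whale {self.whale_id}: testosterone values must be finite and >= 0"
            )
        if self.d15n is not None and np.any(~np.isfinite(self.d15n)):
            raise ValidationError(
                f"whale {self.whale_id}: d15n contains missing values; a whale's "
                "isotope series must be complete or absent entirely"
            )

    @property
    def spacing_cm(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    @property
    def plate_length_cm(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def window(self, win: "AnalysisWindow") -> "HormoneProfile":
        """Restrict the profile to an analysis window [start_cm, end_cm]."""
        if not (0.0 <= win.start_cm < win.end_cm):
            raise ValidationError("window must satisfy 0 <= start < end")
        mask = (self.positions >= win.start_cm - SPACING_TOL) & (
            self.positions <= win.end_cm + SPACING_TOL
        )
        return replace(
            self,
            positions=self.positions[mask],
            testosterone=self.testosterone[mask],
            d15n=None if self.d15n is None else self.d15n[mask],
        )


@dataclass(frozen=True)
class WhaleMetadata:
    """Per-whale collection data and candidate age estimates (years)."""

    whale_id: str
    body_length_m: float
    collection_month: int
    collection_year: int
    aar_age_yr: Optional[float] = None
    length_age_yr: Optional[float] = None
    age_override_yr: Optional[float] = None
    gumline_cut: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.body_length_m) or self.body_length_m <= 0:
            raise ValidationError(
                f"whale {self.whale_id}: body_length_m must be > 0"
            )
        for name in ("aar_age_yr", "length_age_yr", "age_override_yr"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValidationError(f"whale {self.whale_id}: {name} must be > 0")


@dataclass(frozen=True)
class AnalysisWindow:
    """Restrict analysis to part of a plate, e.g. the cycling half of a
    juvenile's plate; in cm from the most recently grown end."""

    start_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_cm < self.end_cm):
            raise ValidationError("AnalysisWindow requires 0 <= start_cm < end_cm")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_profiles(path) -> list[HormoneProfile]:
    """Read a tidy profiles CSV into one validated profile per whale.

    Columns: whale_id, position_cm, testosterone_ng_g, optional d15n_permil.
    A whale whose d15n_permil cells are all empty gets ``d15n=None``; a whale
    with a partially filled isotope column is rejected (the sampling grid is
    complete by design and interpolation is out of scope).
    """
    path = Path(path)
    # round_trip parsing: the default float parser can be one ulp off,
    # breaking read(write(x)) == x exactness
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["whale_id", "position_cm", "testosterone_ng_g"], path)
    has_n = "d15n_permil" in df.columns
    profiles = []
    for wid, g in df.groupby("whale_id", sort=True):
        g = g.sort_values("position_cm")
        d15n = None
        if has_n:
            col = g["d15n_permil"]
            if col.notna().all():
                d15n = col.to_numpy(dtype=float)
            elif col.notna().any():
                raise ValidationError(
                    f"whale {wid}: d15n_permil partially missing; must be complete "
                    "or empty for a whale"
                )
        profiles.append(
            HormoneProfile(
                whale_id=str(wid),
                positions=g["position_cm"].to_numpy(dtype=float),
                testosterone=g["testosterone_ng_g"].to_numpy(dtype=float),
                d15n=d15n,
            )
        )
    return profiles


def write_profiles(profiles: Sequence[HormoneProfile], path) -> Path:
    """Write profiles to a tidy CSV re-readable by :func:`read_profiles`."""
    path = Path(path)
    rows = []
    for p in profiles:
        for i in range(p.n_samples):
            rows.append(
                {
                    "whale_id": p.whale_id,
                    "position_cm": p.positions[i],
                    "testosterone_ng_g": p.testosterone[i],
                    "d15n_permil": p.d15n[i] if p.d15n is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def read_metadata(path) -> list[WhaleMetadata]:
    """Read the whale metadata CSV (one row per whale)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["whale_id", "body_length_m"], path)
    records = []
    for _, row in df.sort_values("whale_id").iterrows():
        records.append(
            WhaleMetadata(
                whale_id=str(row["whale_id"]),
                body_length_m=float(row["body_length_m"]),
                collection_month=int(row.get("collection_month", 1) or 1),
                collection_year=int(row.get("collection_year", 1900) or 1900),
                aar_age_yr=_opt(row.get("aar_age_yr")),
                length_age_yr=_opt(row.get("length_age_yr")),
                age_override_yr=_opt(row.get("age_override_yr")),
                gumline_cut=bool(row.get("gumline_cut", False)),
            )
        )
    return records


def write_metadata(records: Sequence[WhaleMetadata], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "whale_id": m.whale_id,
                "body_length_m": m.body_length_m,
                "collection_month": m.collection_month,
                "collection_year": m.collection_year,
                "aar_age_yr": m.aar_age_yr,
                "length_age_yr": m.length_age_yr,
                "age_override_yr": m.age_override_yr,
                "gumline_cut": m.gumline_cut,
            }
            for m in records
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path
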