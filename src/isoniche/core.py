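"""Core containers shared across the pipeline.

A whisker (vibrissa) is metabolically inert keratin that grows continuously,
so the sequence of δ13C/δ15N values measured in segments cut along its length
is a time series of the animal's foraging history.  Position is measured in mm
from the facial (proximal) end, which holds the most recently grown — hence
oldest-age-at-sampling — material; the distal tip is the earliest growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: day-count convention used to convert whisker growth (mm/day) to years
DAYS_PER_YEAR = 365.25

#: uniform-spacing tolerance for segment positions, mm
SPACING_TOL = 1e-6


class IsonicheError(Exception):
    """Base class for all package errors."""


class EmptySeriesError(IsonicheError):
    """Whisker too short to yield a single segment."""


class InsufficientDataError(IsonicheError):
    """Not enough observations for the requested estimate."""


class IrregularSpacingError(IsonicheError):
    """Segment positions are not uniformly spaced."""


class DegenerateInputError(IsonicheError):
    """Point cloud too small or rank-deficient for an ellipse fit."""


class SchemaError(IsonicheError):
    """Malformed input table."""


@dataclass
class WhiskerSeries:
    """One seal's ordered per-segment isotope record.

    positions are segment-start offsets in mm from the facial end, strictly
    increasing and uniformly spaced; d13C/d15N are per-mil values aligned to
    positions.
    """

    seal_id: str
    sex: str  # "male" | "female"
    positions: np.ndarray
    d13C: np.ndarray
    d15N: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.d13C = np.asarray(self.d13C, dtype=float)
        self.d15N = np.asarray(self.d15N, dtype=float)
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        n = len(self.positions)
        if len(self.d13C) != n or len(self.d15N) != n:
            raise ValueError("positions, d13C and d15N must have equal length")
        if n == 0:
            raise EmptySeriesError(f"seal {self.seal_id}: empty whisker series")
        if n >= 2:
            steps = np.diff(self.positions)
            if np.any(steps <= 0):
                raise IrregularSpacingError(
                    f"seal {self.seal_id}: positions not strictly increasing"
                )
            if np.ptp(steps) > SPACING_TOL:
                raise IrregularSpacingError(
                    f"seal {self.seal_id}: non-uniform segment spacing "
                    f"(range {steps.min():.6g}-{steps.max():.6g} mm)"
                )
        if np.isnan(self.d13C).any() or np.isnan(self.d15N).any():
            raise ValueError(f"seal {self.seal_id}: missing isotope values")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def segment_mm(self) -> float:
        if len(self) < 2:
            raise InsufficientDataError("spacing undefined for a single segment")
        return float(self.positions[1] - self.positions[0])

    @property
    def span_mm(self) -> float:
        """Sampled whisker span: last segment start + one segment length."""
        if len(self) < 2:
            return float(self.positions[0])
        return float(self.positions[-1] - self.positions[0] + self.segment_mm)


@dataclass
class Chronology:
    """Per-segment age estimates for one whisker.

    Ages are strictly decreasing with position: the facial end (position 0)
    is the newest growth and therefore carries the greatest age at sampling.
    ``is_minimum_age`` marks female chronologies anchored at a worn/broken
    tip, where only a minimum age is identifiable.
    """

    seal_id: str
    growth_rate: float  # mm/day
    rate_source: str  # "wavelet" | "cohort_mean" | "provided"
    age_at_facial_end: float  # years
    positions: np.ndarray
    ages: np.ndarray  # years, aligned to positions
    is_minimum_age: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if len(self.ages) >= 2 and not np.all(np.diff(self.ages) < 0):
            raise ValueError("ages must be strictly decreasing with position")
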