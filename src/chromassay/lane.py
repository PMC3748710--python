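"""Electrophoretic mobility model and 1-D lane profiles.

These two types are shared by the simulation side (which renders lanes)
and the analysis side (which quantifies them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, RangeError

__all__ = ["GelModel", "LaneProfile"]


@dataclass(frozen=True)
class GelModel:
    """Log-linear mobility model: migration = intercept + slope * log10(length).

    Migration is measured in sample points ("pixels") along the lane axis,
    increasing in the direction of travel, so ``slope`` must be negative
    (longer fragments migrate less). The model is only trusted between
    ``min_length`` and ``max_length`` base pairs.
    """

    intercept: float = 1200.0
    slope: float = -300.0
    band_width: float = 8.0
    axis_length: int = 1000
    noise_sd: float = 1.0
    baseline_drift: float = 0.0
    min_length: float = 50.0
    max_length: float = 8000.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ParameterError("slope must be negative: migration decreases with length")
        if self.band_width <= 0:
            raise ParameterError("band_width must be > 0")
        if self.axis_length < 100:
            raise ParameterError("axis_length must be >= 100")
        if not (0 < self.min_length < self.max_length):
            raise ParameterError("require 0 < min_length < max_length")
        if self.noise_sd < 0 or self.baseline_drift < 0:
            raise ParameterError("noise_sd and baseline_drift must be >= 0")

    def migration(self, length):
        """Map fragment length (bp) to migration coordinate.

        Raises :class:`RangeError` for lengths outside the calibrated range.
        """
        arr = np.asarray(length, dtype=float)
        if np.any(arr < self.min_length) or np.any(arr > self.max_length):
            raise RangeError(
                f"fragment length outside calibrated range "
                f"[{self.min_length}, {self.max_length}] bp"
            )
        out = self.intercept + self.slope * np.log10(arr)
        return out if out.ndim else float(out)

    def length_from_migration(self, migration):
        """Inverse of :meth:`migration` (exact for the log-linear model)."""
        arr = np.asarray(migration, dtype=float)
        out = 10.0 ** ((arr - self.intercept) / self.slope)
        if np.any(out < self.min_length * 0.999) or np.any(out > self.max_length * 1.001):
            raise RangeError("migration coordinate outside calibrated range")
        return out if out.ndim else float(out)

    def positions(self) -> np.ndarray:
        return np.arange(self.axis_length, dtype=float)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "band_width": self.band_width,
            "axis_length": self.axis_length,
            "noise_sd": self.noise_sd,
            "baseline_drift": self.baseline_drift,
            "min_length": self.min_length,
            "max_length": self.max_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GelModel":
        return cls(**{k: (int(v) if k == "axis_length" else float(v)) for k, v in d.items()})


@dataclass
class LaneProfile:
    """A single densitometry trace: intensity as a function of migration.

    ``positions`` must be strictly increasing. ``calibration``, if present,
    maps fragment length to migration coordinate for this lane.
    """

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = "lane"
    calibration: GelModel | None = None
    background_subtracted: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ParameterError("positions and intensities must be 1-D and equal length")
        if self.positions.size < 2:
            raise ParameterError("a profile needs at least two samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensities must be finite")

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    @property
    def sample_spacing(self) -> float:
        return float(np.median(np.diff(self.positions)))

    def with_intensities(self, intensities: np.ndarray, **changes) -> "LaneProfile":
        return replace(self, intensities=np.asarray(intensities, dtype=float), **changes)

    def total_signal(self) -> float:
        """Trapezoidal integral of the whole trace."""
        return float(np.trapezoid(self.intensities, self.positions))
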