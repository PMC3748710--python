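"""Percent-supercoiling quantification of supercoiling assay lanes.

Species intensities are trapezoidal integrals of a background-subtracted
trace over three disjoint migration windows (supercoiled, relaxed
topoisomer cluster, nicked open circular). The convention is:

    percent supercoiling = 100 * SC / (SC + Rel + N)

i.e. nicked DNA counts in the total but never in the supercoiled
numerator, because the fraction of nicked molecules that is packaged
into chromatin cannot be determined from the gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ComparabilityError, ParameterError, UndefinedResultError
from .lane import LaneProfile

__all__ = ["SupercoilingResult", "quantify_supercoiling", "delta_supercoiling"]

SPECIES = ("sc", "rel", "nick")


@dataclass
class SupercoilingResult:
    lane_id: str
    sc_intensity: float
    relaxed_intensity: float
    nicked_intensity: float
    percent_supercoiling: float
    windows: dict = field(default_factory=dict)
    reference_lane_id: str | None = None
    delta_percent: float | None = None


def _validate_windows(windows: dict) -> dict[str, tuple[float, float]]:
    missing = [k for k in SPECIES if k not in windows]
    if missing:
        raise ParameterError(f"missing species windows: {missing}")
    clean = {k: (float(windows[k][0]), float(windows[k][1])) for k in SPECIES}
    for name, (lo, hi) in clean.items():
        if not lo < hi:
            raise ParameterError(f"{name} window must satisfy lo < hi")
    spans = sorted(clean.values())
    for (lo1, hi1), (lo2, hi2) in zip(spans[:-1], spans[1:]):
        if hi1 > lo2:
            raise ParameterError("species windows must not overlap")
    return clean


def _integrate(profile: LaneProfile, lo: float, hi: float) -> float:
    x, y = profile.positions, profile.intensities
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        return 0.0
    return max(float(np.trapezoid(y[mask], x[mask])), 0.0)


def quantify_supercoiling(profile: LaneProfile, windows: dict) -> SupercoilingResult:
    """Integrate the three species windows and apply the percent formula.

    Raises :class:`UndefinedResultError` (not 0) when the lane carries no
    signal at all: 0/0 is not a measurement.
    """
    clean = _validate_windows(windows)
    sc = _integrate(profile, *clean["sc"])
    rel = _integrate(profile, *clean["rel"])
    nick = _integrate(profile, *clean["nick"])
    total = sc + rel + nick
    if total <= 0:
        raise UndefinedResultError(
            f"lane {profile.lane_id!r}: zero total signal in all species windows"
        )
    return SupercoilingResult(
        lane_id=profile.lane_id,
        sc_intensity=sc,
        relaxed_intensity=rel,
        nicked_intensity=nick,
        percent_supercoiling=100.0 * sc / total,
        windows=clean,
    )


def delta_supercoiling(sample: SupercoilingResult, reference: SupercoilingResult) -> float:
    """Change in percent supercoiling relative to a reference lane
    (typically the matched AMP-PNP or zero-time lane of the same series).

    Negative values are permitted (remodelers can reduce supercoiling).
    Both results must have been quantified under identical windows.
    """
    if sample.windows != reference.windows:
        raise ComparabilityError(
            "sample and reference were quantified with different windows"
        )
    delta = sample.percent_supercoiling - reference.percent_supercoiling
    sample.reference_lane_id = reference.lane_id
    sample.delta_percent = delta
    return delta
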