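"""Lane-profile processing and the nucleosome spacing index.

The spacing index of a partial-MNase ladder trace is the mean of the
di- and tri-nucleosome band peak heights minus the height of the valley
between them:

    index = 0.5 * (P2 + P3) - V

Heights, not areas, are used, and indices are only comparable across
lanes run under identical electrophoretic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    BandNotFoundError,
    DegenerateProfileError,
    ParameterError,
)
from .lane import GelModel, LaneProfile

__all__ = [
    "BandWindows",
    "BandLocations",
    "SpacingIndexResult",
    "subtract_background",
    "locate_bands",
    "compute_spacing_index",
    "extract_lane_profiles",
]


@dataclass(frozen=True)
class BandWindows:
    """Migration-coordinate intervals for the di- and tri-nucleosome bands
    (and optionally the mononucleosome band).

    Because smaller fragments migrate further, the di window must sit at
    strictly larger migration coordinates than the tri window.
    """

    di: tuple[float, float]
    tri: tuple[float, float]
    mono: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, w in (("di", self.di), ("tri", self.tri), ("mono", self.mono)):
            if w is not None and not w[0] < w[1]:
                raise ParameterError(f"{name} window must satisfy lo < hi")
        if self.tri[1] > self.di[0]:
            raise ParameterError(
                "windows overlap or are mis-ordered: the tri window must lie "
                "at smaller migration than the di window"
            )
        if self.mono is not None and self.mono[0] < self.di[1]:
            raise ParameterError("mono window must lie at larger migration than di")

    @classmethod
    def from_calibration(
        cls,
        gel: GelModel,
        repeat_bp: int,
        footprint: int = 147,
        half_width_frac: float = 0.2,
    ) -> "BandWindows":
        """Derive windows from a mobility model and the expected repeat.

        The k-nucleosome band of a trimmed partial digest runs at the
        outer-footprint span ``k*repeat - mean_linker`` where
        ``mean_linker = repeat - footprint``. Window half-width defaults
        to 20% of the di-tri band spacing.
        """
        if repeat_bp <= footprint:
            raise ParameterError("repeat_bp must exceed the footprint")
        linker = repeat_bp - footprint
        m1 = gel.migration(float(footprint))
        m2 = gel.migration(float(2 * repeat_bp - linker))
        m3 = gel.migration(float(3 * repeat_bp - linker))
        w = half_width_frac * (m2 - m3)
        return cls(di=(m2 - w, m2 + w), tri=(m3 - w, m3 + w), mono=(m1 - w, m1 + w))


@dataclass
class BandLocations:
    p2_pos: float
    p2_height: float
    p2_is_local_max: bool
    p3_pos: float
    p3_height: float
    p3_is_local_max: bool
    v_pos: float
    v_height: float


@dataclass
class SpacingIndexResult:
    """P2, P3, the inter-peak valley V, and the index 0.5*(P2+P3) - V.

    The valley symbol appears as both "V2" and "V3" in source material;
    it is simply the minimum strictly between the two peaks.
    """

    lane_id: str
    P2: float
    P3: float
    V: float
    index: float
    p2_pos: float
    p3_pos: float
    v_pos: float


def subtract_background(
    profile: LaneProfile,
    method: str = "rolling_minimum",
    window: float | None = None,
) -> LaneProfile:
    """Estimate and remove background staining; result floored at zero.

    ``rolling_minimum`` subtracts a running-minimum baseline (window in
    migration units; default 8x the gel band width when calibration is
    available). ``linear_anchors`` fits a line through the minima of the
    first and last window-sized chunks. Idempotent within tolerance when
    the window exceeds the widest peak.
    """
    y = profile.intensities
    spacing = profile.sample_spacing
    if window is None:
        bw = profile.calibration.band_width if profile.calibration else None
        window = 8.0 * bw if bw else profile.span / 10.0
    if window <= 0:
        raise ParameterError("window must be > 0")
    if window > profile.span:
        raise ParameterError(
            f"window ({window}) exceeds the profile span ({profile.span})"
        )
    size = max(3, int(round(window / spacing)))
    if size % 2 == 0:
        size += 1
    if method == "rolling_minimum":
        baseline = ndimage.minimum_filter(y, size=size, mode="nearest")
    elif method == "linear_anchors":
        k = max(1, size // 2)
        i0 = int(np.argmin(y[:k]))
        i1 = int(y.size - k + np.argmin(y[-k:]))
        x = profile.positions
        if x[i1] == x[i0]:
            baseline = np.full_like(y, min(y[i0], y[i1]))
        else:
            slope = (y[i1] - y[i0]) / (x[i1] - x[i0])
            baseline = y[i0] + slope * (x - x[i0])
    else:
        raise ParameterError(f"unknown background method: {method!r}")
    corrected = np.maximum(y - baseline, 0.0)
    return profile.with_intensities(corrected, background_subtracted=True)


def _window_max(profile: LaneProfile, window: tuple[float, float], name: str):
    x, y = profile.positions, profile.intensities
    mask = (x >= window[0]) & (x <= window[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise BandNotFoundError(
            f"{name} window [{window[0]}, {window[1]}] contains no profile samples"
        )
    local = int(np.argmax(y[idx]))
    i = int(idx[local])
    is_local_max = 0 < local < idx.size - 1
    return float(x[i]), float(y[i]), is_local_max


def locate_bands(profile: LaneProfile, windows: BandWindows) -> BandLocations:
    """Peak positions/heights in the di and tri windows, and the minimum
    strictly between the two peak positions.

    A peak whose maximum falls on a window edge is flagged as a
    non-local extremum rather than rejected. Valley ties are broken
    toward the midpoint between the peaks.
    """
    p2_pos, p2_h, p2_loc = _window_max(profile, windows.di, "di")
    p3_pos, p3_h, p3_loc = _window_max(profile, windows.tri, "tri")
    x, y = profile.positions, profile.intensities
    between = np.flatnonzero((x > p3_pos) & (x < p2_pos))
    if between.size == 0:
        raise DegenerateProfileError(
            "di and tri peaks are coincident or adjacent: no interior valley"
        )
    vy = y[between]
    vmin = vy.min()
    ties = between[vy == vmin]
    mid = 0.5 * (p2_pos + p3_pos)
    v_i = int(ties[np.argmin(np.abs(x[ties] - mid))])
    return BandLocations(
        p2_pos=p2_pos,
        p2_height=p2_h,
        p2_is_local_max=p2_loc,
        p3_pos=p3_pos,
        p3_height=p3_h,
        p3_is_local_max=p3_loc,
        v_pos=float(x[v_i]),
        v_height=float(y[v_i]),
    )


def compute_spacing_index(profile: LaneProfile, windows: BandWindows) -> SpacingIndexResult:
    """Spacing index 0.5*(P2 + P3) - V of a background-subtracted trace."""
    bands = locate_bands(profile, windows)
    index = 0.5 * (bands.p2_height + bands.p3_height) - bands.v_height
    return SpacingIndexResult(
        lane_id=profile.lane_id,
        P2=bands.p2_height,
        P3=bands.p3_height,
        V=bands.v_height,
        index=index,
        p2_pos=bands.p2_pos,
        p3_pos=bands.p3_pos,
        v_pos=bands.v_pos,
    )


def extract_lane_profiles(
    image,
    lane_bounds,
    wells_at_top: bool = True,
    lane_ids=None,
) -> list[LaneProfile]:
    """Average pixel columns of each lane of a grayscale gel image.

    ``image`` is a 2-D array or a path to an 8/16-bit grayscale TIFF/PNG.
    ``lane_bounds`` are non-overlapping half-open column intervals
    ``(lo, hi)``. The migration coordinate is the row index, increasing
    downward from the wells by default.
    """
    if not isinstance(image, np.ndarray):
        import imageio.v3 as iio

        image = iio.imread(image)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("image must be single-channel (2-D)")
    nrows, ncols = image.shape
    bounds = [(int(lo), int(hi)) for lo, hi in lane_bounds]
    for lo, hi in bounds:
        if lo < 0 or hi > ncols or lo >= hi:
            raise ParameterError(f"lane interval ({lo}, {hi}) outside image columns")
    for (lo1, hi1), (lo2, hi2) in zip(bounds[:-1], bounds[1:]):
        if hi1 > lo2:
            raise ParameterError("lane intervals must be non-overlapping and ordered")
    rows = np.arange(nrows, dtype=float)
    data = image if wells_at_top else image[::-1]
    out = []
    for i, (lo, hi) in enumerate(bounds):
        trace = data[:, lo:hi].mean(axis=1)
        lane_id = lane_ids[i] if lane_ids is not None else f"lane{i + 1}"
        out.append(
            LaneProfile(
                positions=rows,
                intensities=trace,
                lane_id=lane_id,
                metadata={"columns": (lo, hi)},
            )
        )
    return out
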