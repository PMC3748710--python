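"""CSV / BED / image readers and writers.

All text outputs are comma-separated UTF-8 with ``#``-prefixed metadata
header lines, so files are human-inspectable, diff-able, and round-trip
exactly (floats written with repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParseError
from .kinetics import TimeCourse
from .lane import GelModel, LaneProfile
from .synthetic_gel import FragmentSample, NucleosomeArray

__all__ = [
    "write_lane_profile",
    "read_lane_profile",
    "write_fragment_sample",
    "read_fragment_sample",
    "write_array_bed",
    "write_spacing_results",
    "write_supercoiling_results",
    "write_time_course",
    "read_time_course",
    "read_kobs_table",
]

_FLOAT = "%.17g"


def _meta_lines(meta: dict) -> list[str]:
    return [f"# {k}={json.dumps(v)}" for k, v in meta.items()]


def _read_csv(path, required: tuple[str, ...]):
    """Parse a headered CSV with '#' metadata lines; returns (meta, columns)."""
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = json.loads(val)
                    except json.JSONDecodeError:
                        meta[key.strip()] = val
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                for col in required:
                    if col not in header:
                        raise ParseError(
                            f"{path}: missing required column", line=lineno, column=col
                        )
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: expected {len(header)} fields, got {len(parts)}",
                    line=lineno,
                )
            rows.append(parts)
    if header is None:
        raise ParseError(f"{path}: no header row found")
    cols: dict[str, list[str]] = {h: [] for h in header}
    for r in rows:
        for h, v in zip(header, r):
            cols[h].append(v)
    return meta, cols


def _floats(values: list[str], path, column: str) -> np.ndarray:
    try:
        return np.array([float(v) for v in values])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})", column=column) from exc


def write_lane_profile(profile: LaneProfile, path) -> None:
    meta: dict = {"lane_id": profile.lane_id,
                  "background_subtracted": profile.background_subtracted}
    if profile.calibration is not None:
        meta["calibration"] = profile.calibration.to_dict()
    for k, v in profile.metadata.items():
        try:
            json.dumps(v)
        except TypeError:
            continue
        meta[f"meta_{k}"] = v
    lines = _meta_lines(meta)
    lines.append("migration_px,intensity")
    for x, y in zip(profile.positions, profile.intensities):
        lines.append(f"{_FLOAT % x},{_FLOAT % y}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_lane_profile(path) -> LaneProfile:
    meta, cols = _read_csv(path, required=("migration_px", "intensity"))
    calibration = None
    if isinstance(meta.get("calibration"), dict):
        calibration = GelModel.from_dict(meta["calibration"])
    extra = {k[5:]: v for k, v in meta.items() if k.startswith("meta_")}
    return LaneProfile(
        positions=_floats(cols["migration_px"], path, "migration_px"),
        intensities=_floats(cols["intensity"], path, "intensity"),
        lane_id=str(meta.get("lane_id", Path(path).stem)),
        calibration=calibration,
        background_subtracted=bool(meta.get("background_subtracted", False)),
        metadata=extra,
    )


def write_fragment_sample(sample: FragmentSample, path) -> None:
    lines = _meta_lines({"provenance": sample.provenance})
    lines.append("length_bp,count")
    for length, count in zip(sample.lengths, sample.counts):
        lines.append(f"{int(length)},{int(count)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_fragment_sample(path) -> FragmentSample:
    meta, cols = _read_csv(path, required=("length_bp", "count"))
    return FragmentSample(
        lengths=_floats(cols["length_bp"], path, "length_bp").astype(int),
        counts=_floats(cols["count"], path, "count").astype(int),
        provenance=str(meta.get("provenance", "")),
    )


def write_array_bed(array: NucleosomeArray, path, template_id: str = "template") -> None:
    """BED-like 0-based half-open footprint intervals.

    A nucleosome spanning the circular origin is written with end >
    template_length; consumers treating the template as linear should
    wrap coordinates themselves.
    """
    lines = [
        f"# template_length={array.template_length}",
        f"# circular={json.dumps(array.circular)}",
        f"# footprint={array.footprint}",
    ]
    for start, end in array.protected_intervals():
        s = int(start) % array.template_length if array.circular else max(int(start), 0)
        lines.append(f"{template_id}\t{s}\t{s + array.footprint}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_spacing_results(results, path) -> None:
    lines = ["lane_id,P2,P3,V,index,p2_pos,p3_pos,v_pos"]
    for r in results:
        lines.append(
            ",".join(
                [r.lane_id]
                + [_FLOAT % v for v in (r.P2, r.P3, r.V, r.index, r.p2_pos, r.p3_pos, r.v_pos)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_supercoiling_results(results, path) -> None:
    lines = ["lane_id,sc,rel,nick,percent_supercoiling,reference_lane_id,delta_percent"]
    for r in results:
        delta = "" if r.delta_percent is None else _FLOAT % r.delta_percent
        ref = r.reference_lane_id or ""
        lines.append(
            ",".join(
                [
                    r.lane_id,
                    _FLOAT % r.sc_intensity,
                    _FLOAT % r.relaxed_intensity,
                    _FLOAT % r.nicked_intensity,
                    _FLOAT % r.percent_supercoiling,
                    ref,
                    delta,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_time_course(tc: TimeCourse, path) -> None:
    meta: dict = {"observable": tc.observable}
    has_conc = tc.protein_concentration is not None
    lines = _meta_lines(meta)
    lines.append("time_min,value" + (",protein_nM" if has_conc else ""))
    for t, v in zip(tc.times, tc.values):
        row = f"{_FLOAT % t},{_FLOAT % v}"
        if has_conc:
            row += f",{_FLOAT % tc.protein_concentration}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_time_course(path) -> TimeCourse:
    meta, cols = _read_csv(path, required=("time_min", "value"))
    conc = None
    if "protein_nM" in cols and cols["protein_nM"]:
        conc = float(cols["protein_nM"][0])
    return TimeCourse(
        times=_floats(cols["time_min"], path, "time_min"),
        values=_floats(cols["value"], path, "value"),
        observable=str(meta.get("observable", "")),
        protein_concentration=conc,
    )


def read_kobs_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Substrate-saturation table: columns substrate_nM, kobs_per_min."""
    _, cols = _read_csv(path, required=("substrate_nM", "kobs_per_min"))
    return (
        _floats(cols["substrate_nM"], path, "substrate_nM"),
        _floats(cols["kobs_per_min"], path, "kobs_per_min"),
    )
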