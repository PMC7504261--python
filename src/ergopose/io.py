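"""Readers and writers for the kinematic time-series files.

Two dialects are supported:

* **csv** — delimited text with a 2-line header.  Line 1 is a metadata
  comment, e.g.::

      # ergopose-kinematics v1; kind=joint_angles; frame_rate_hz=60; units=deg; up_axis=z; forward_axis=x

  Line 2 names the columns (``time`` plus one column per channel).  Floats
  are written with 17 significant digits so a write/read round trip is
  bit-exact.

* **xml** — a minimal mocap-session dialect (one ``<frame>`` element per
  frame, one ``<joint>``/``<segment>`` element per body part with the three
  components as attributes).  Convenient for tool interop; not bit-exact.

Units are asserted on read: angles must be degrees, positions metres.
Unknown extra columns are ignored with a warning; missing mandatory channels
and non-monotone timestamps are errors.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .body import (
    ANGLE_CHANNELS,
    AXES,
    COMPONENTS,
    JOINTS,
    POSITION_CHANNELS,
    SEGMENTS,
    canonical_channel,
)
from .errors import ChannelMissingError, FormatError, SegmentCountError
from .series import JointAngleSeries, SegmentPositionSeries

_MAGIC = "# ergopose-kinematics v1"


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "xml"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "xml" if path.suffix.lower() in (".xml", ".mvnx") else "csv"


def _parse_meta(line: str) -> dict[str, str]:
    if not line.startswith(_MAGIC):
        raise FormatError(
            f"file does not start with the {_MAGIC!r} metadata line"
        )
    meta = {}
    for item in line[len(_MAGIC):].split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def _format_meta(kind: str, frame_rate: float, units: str, up: str, fwd: str) -> str:
    return (
        f"{_MAGIC}; kind={kind}; frame_rate_hz={frame_rate:.17g}; "
        f"units={units}; up_axis={up}; forward_axis={fwd}"
    )


def _read_table(path: Path, kind: str, units: str) -> tuple[dict, pd.DataFrame]:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    meta = _parse_meta(lines[0])
    if meta.get("kind") != kind:
        raise FormatError(
            f"{path}: expected kind={kind}, file declares kind={meta.get('kind')!r}"
        )
    if meta.get("units") != units:
        raise FormatError(
            f"{path}: expected units={units}, file declares {meta.get('units')!r}"
        )
    if "frame_rate_hz" not in meta:
        raise FormatError(f"{path}: header must declare frame_rate_hz")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[1:])), float_precision="round_trip")
    return meta, df


def _resolve_columns(
    df: pd.DataFrame, required: tuple[str, ...], path: Path
) -> pd.DataFrame:
    rename, unknown = {}, []
    for col in df.columns:
        canon = canonical_channel(col)
        if canon is None:
            unknown.append(col)
        elif canon != col:
            rename[col] = canon
    if rename:
        df = df.rename(columns=rename)
    if unknown:
        warnings.warn(
            f"{path}: ignoring {len(unknown)} unknown channel(s): "
            + ", ".join(unknown[:5])
            + ("..." if len(unknown) > 5 else ""),
            stacklevel=3,
        )
        df = df.drop(columns=unknown)
    if "time" not in df.columns:
        raise ChannelMissingError("time")
    for ch in required:
        if ch not in df.columns:
            raise ChannelMissingError(ch)
    return df


def read_joint_angle_series(path, dialect: str | None = None) -> JointAngleSeries:
    """Read a joint-angle time series (22 joints x 3 components, degrees).

    ``dialect`` is ``"csv"``, ``"xml"``, or ``None`` to infer from the file
    extension.  Raises :class:`ChannelMissingError` when a mandatory channel
    is absent and :class:`FormatError` for malformed headers or non-monotone
    timestamps.
    """
    path = Path(path)
    if _infer_dialect(path, dialect) == "xml":
        return _read_angles_xml(path)
    meta, df = _read_table(path, "joint_angles", "deg")
    df = _resolve_columns(df, ANGLE_CHANNELS, path)
    angles = df[list(ANGLE_CHANNELS)].to_numpy(dtype=float).reshape(len(df), 22, 3)
    return JointAngleSeries(
        frame_rate=float(meta["frame_rate_hz"]),
        timestamps=df["time"].to_numpy(dtype=float),
        angles=angles,
    )


def read_segment_position_series(
    path, dialect: str | None = None, check_rigid: bool = True
) -> SegmentPositionSeries:
    """Read a segment-position time series (23 segments x 3 axes, metres).

    Applies the rigid-body sanity check (connected-segment distances must
    vary < 5% over the series) unless ``check_rigid=False``.
    """
    path = Path(path)
    if _infer_dialect(path, dialect) == "xml":
        series = _read_positions_xml(path)
    else:
        meta, df = _read_table(path, "segment_positions", "m")
        present = {
            canonical_channel(c) for c in df.columns if canonical_channel(c)
        }
        n_segments = len(
            {ch.rsplit("_", 1)[0] for ch in present if ch != "time"}
        )
        if 0 < n_segments < 23:
            raise SegmentCountError(
                f"{path}: position file carries {n_segments} segments, expected 23"
            )
        df = _resolve_columns(df, POSITION_CHANNELS, path)
        positions = (
            df[list(POSITION_CHANNELS)].to_numpy(dtype=float).reshape(len(df), 23, 3)
        )
        series = SegmentPositionSeries(
            frame_rate=float(meta["frame_rate_hz"]),
            timestamps=df["time"].to_numpy(dtype=float),
            positions=positions,
            up_axis=meta.get("up_axis", "z"),
            forward_axis=meta.get("forward_axis", "x"),
        )
    if check_rigid:
        series.check_rigid_lengths()
    return series


def write_joint_angle_series(series: JointAngleSeries, path) -> None:
    """Write the CSV dialect; round-trips bit-exactly through the reader."""
    path = Path(path)
    header = _format_meta("joint_angles", series.frame_rate, "deg", "z", "x")
    df = series.to_dataframe()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_segment_position_series(series: SegmentPositionSeries, path) -> None:
    path = Path(path)
    header = _format_meta(
        "segment_positions", series.frame_rate, "m", series.up_axis, series.forward_axis
    )
    df = series.to_dataframe()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


# --- minimal XML dialect -------------------------------------------------

def write_joint_angle_series_xml(series: JointAngleSeries, path) -> None:
    root = ET.Element(
        "mocap",
        kind="joint_angles",
        frame_rate_hz=repr(series.frame_rate),
        units="deg",
    )
    for i in range(series.n_frames):
        fr = ET.SubElement(root, "frame", time=repr(float(series.timestamps[i])))
        for j, joint in enumerate(series.joint_names):
            ET.SubElement(
                fr,
                "joint",
                name=joint,
                **{
                    comp: repr(float(series.angles[i, j, c]))
                    for c, comp in enumerate(COMPONENTS)
                },
            )
    ET.ElementTree(root).write(path)


def _read_angles_xml(path: Path) -> JointAngleSeries:
    root = ET.parse(path).getroot()
    if root.get("kind") != "joint_angles":
        raise FormatError(f"{path}: expected kind=joint_angles")
    if root.get("units", "deg") != "deg":
        raise FormatError(f"{path}: angle units must be degrees")
    frames = root.findall("frame")
    times = [float(f.get("time", i)) for i, f in enumerate(frames)]
    angles = np.zeros((len(frames), 22, 3))
    jindex = {j: k for k, j in enumerate(JOINTS)}
    for i, f in enumerate(frames):
        seen = set()
        for el in f.findall("joint"):
            name = el.get("name")
            if name not in jindex:
                continue
            seen.add(name)
            for c, comp in enumerate(COMPONENTS):
                angles[i, jindex[name], c] = float(el.get(comp, 0.0))
        missing = set(JOINTS) - seen
        if missing:
            raise ChannelMissingError(sorted(missing)[0])
    return JointAngleSeries(
        frame_rate=float(root.get("frame_rate_hz")),
        timestamps=np.asarray(times),
        angles=angles,
    )


def write_segment_position_series_xml(series: SegmentPositionSeries, path) -> None:
    root = ET.Element(
        "mocap",
        kind="segment_positions",
        frame_rate_hz=repr(series.frame_rate),
        units="m",
        up_axis=series.up_axis,
        forward_axis=series.forward_axis,
    )
    for i in range(series.n_frames):
        fr = ET.SubElement(root, "frame", time=repr(float(series.timestamps[i])))
        for s, seg in enumerate(series.segment_names):
            ET.SubElement(
                fr,
                "segment",
                name=seg,
                **{
                    ax: repr(float(series.positions[i, s, a]))
                    for a, ax in enumerate(AXES)
                },
            )
    ET.ElementTree(root).write(path)


def _read_positions_xml(path: Path) -> SegmentPositionSeries:
    root = ET.parse(path).getroot()
    if root.get("kind") != "segment_positions":
        raise FormatError(f"{path}: expected kind=segment_positions")
    if root.get("units", "m") != "m":
        raise FormatError(f"{path}: position units must be metres")
    frames = root.findall("frame")
    times = [float(f.get("time", i)) for i, f in enumerate(frames)]
    positions = np.zeros((len(frames), 23, 3))
    sindex = {s: k for k, s in enumerate(SEGMENTS)}
    for i, f in enumerate(frames):
        seen = set()
        for el in f.findall("segment"):
            name = el.get("name")
            if name not in sindex:
                continue
            seen.add(name)
            for a, ax in enumerate(AXES):
                positions[i, sindex[name], a] = float(el.get(ax, 0.0))
        if len(seen) != 23:
            raise SegmentCountError(
                f"{path}: frame {i} carries {len(seen)} segments, expected 23"
            )
    return SegmentPositionSeries(
        frame_rate=float(root.get("frame_rate_hz")),
        timestamps=np.asarray(times),
        positions=positions,
        up_axis=root.get("up_axis", "z"),
        forward_axis=root.get("forward_axis", "x"),
    )
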