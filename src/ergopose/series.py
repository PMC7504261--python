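"""In-memory time-series containers for kinematic data.

All containers are thin wrappers around numpy arrays with validation.  Angles
are degrees, positions metres, time seconds from the first frame; frames are
0-indexed.  Missing frames are a hard error everywhere — risk scores are
per-frame quantities and silent gap-filling would corrupt them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body import ANGLE_CHANNELS, AXES, COMPONENTS, JOINTS, PARENT_MAP, POSITION_CHANNELS, SEGMENTS
from .errors import (
    EmptyInputError,
    FormatError,
    MissingFramesError,
    SegmentCountError,
)

#: Joints of the sagittal linkage chain, distal hand end last.
LINKAGE_JOINTS: tuple[str, ...] = (
    "ankle", "knee", "hip", "l5s1", "shoulder", "elbow", "wrist", "hand",
)

#: Linkage segments as (name, proximal joint, distal joint).
LINKAGE_SEGMENTS: tuple[tuple[str, str, str], ...] = (
    ("shank", "ankle", "knee"),
    ("thigh", "knee", "hip"),
    ("pelvis", "hip", "l5s1"),
    ("trunk", "l5s1", "shoulder"),
    ("upper_arm", "shoulder", "elbow"),
    ("forearm", "elbow", "wrist"),
    ("hand", "wrist", "hand"),
)


def _check_timestamps(timestamps: np.ndarray, frame_rate: float) -> None:
    if timestamps.ndim != 1 or timestamps.size == 0:
        raise EmptyInputError("series must contain at least one frame")
    d = np.diff(timestamps)
    if timestamps.size > 1 and not np.all(d > 0):
        raise FormatError("timestamps must be strictly increasing")
    if frame_rate <= 0:
        raise FormatError(f"frame rate must be positive, got {frame_rate}")
    if timestamps.size > 2:
        # a gap shows up as a frame interval well above the nominal period
        if np.max(d) > 1.5 * np.median(d):
            raise MissingFramesError(
                "gap detected in timestamps; missing frames are an error, "
                "not interpolated"
            )


@dataclass
class JointAngleSeries:
    """Per-frame 3-component angles (degrees) for the 22-joint body model.

    ``angles`` has shape (frames, 22, 3) with components ordered
    (flexion/extension, abduction/adduction, internal/external rotation).
    """

    frame_rate: float
    timestamps: np.ndarray
    angles: np.ndarray
    joint_names: tuple[str, ...] = JOINTS

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        _check_timestamps(self.timestamps, self.frame_rate)
        expected = (self.timestamps.size, len(self.joint_names), 3)
        if self.angles.shape != expected:
            raise FormatError(
                f"angle array shape {self.angles.shape} != expected {expected}"
            )
        if np.any(np.abs(self.angles) > 360.0):
            raise FormatError("angle magnitudes must not exceed 360 degrees")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def angle(self, joint: str, component: str) -> np.ndarray:
        """Time series of one channel, e.g. ``angle('jRightElbow', 'flexion')``."""
        j = self.joint_names.index(joint)
        c = COMPONENTS.index(component)
        return self.angles[:, j, c]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.angles.reshape(self.n_frames, -1), columns=list(ANGLE_CHANNELS)
        )
        df.insert(0, "time", self.timestamps)
        return df


@dataclass
class SegmentPositionSeries:
    """Per-frame global 3D positions (metres) for the 23-segment body model.

    ``positions`` has shape (frames, 23, 3).  The coordinate convention
    (which axis is up, which is forward) is carried by the series so the
    sagittal projection can identify gravity.
    """

    frame_rate: float
    timestamps: np.ndarray
    positions: np.ndarray
    segment_names: tuple[str, ...] = SEGMENTS
    up_axis: str = "z"
    forward_axis: str = "x"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        _check_timestamps(self.timestamps, self.frame_rate)
        if len(self.segment_names) != 23:
            raise SegmentCountError(
                f"expected 23 segments, got {len(self.segment_names)}"
            )
        expected = (self.timestamps.size, 23, 3)
        if self.positions.shape != expected:
            raise FormatError(
                f"position array shape {self.positions.shape} != expected {expected}"
            )
        self.up_axis = self.up_axis.lower()
        self.forward_axis = self.forward_axis.lower()
        if self.up_axis not in AXES or self.forward_axis not in AXES:
            raise FormatError("up/forward axes must be one of x, y, z")
        if self.up_axis == self.forward_axis:
            raise FormatError("up and forward axes must differ")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def position(self, segment: str) -> np.ndarray:
        """(frames, 3) trajectory of one segment origin."""
        return self.positions[:, self.segment_names.index(segment), :]

    def check_rigid_lengths(self, tolerance: float = 0.05) -> None:
        """Rigid-body sanity check: inter-segment distances for connected
        segments must vary by less than ``tolerance`` (fraction of the mean)
        over the series.  Raises :class:`FormatError` on violation."""
        if self.n_frames < 2:
            return
        idx = {s: i for i, s in enumerate(self.segment_names)}
        for seg, parent in PARENT_MAP.items():
            if parent is None or seg not in idx or parent not in idx:
                continue
            d = np.linalg.norm(
                self.positions[:, idx[seg]] - self.positions[:, idx[parent]], axis=1
            )
            mean = d.mean()
            if mean < 1e-9:
                continue  # coincident origins (e.g. virtual points) carry no length
            if (d.max() - d.min()) / mean > tolerance:
                raise FormatError(
                    f"distance {parent}->{seg} varies more than "
                    f"{tolerance:.0%} over the series; positions are not "
                    "rigid-body consistent"
                )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.positions.reshape(self.n_frames, -1), columns=list(POSITION_CHANNELS)
        )
        df.insert(0, "time", self.timestamps)
        return df


@dataclass
class LinkageStateSeries:
    """Sagittal-plane state of the 8-joint linkage chain.

    ``coords`` has shape (frames, 8, 2) holding (horizontal, vertical)
    coordinates in metres for the joints in :data:`LINKAGE_JOINTS`; the
    vertical axis is gravity-aligned.  ``inclinations_deg`` maps each linkage
    segment to its per-frame inclination from the horizontal (degrees,
    positive above the horizon, measured proximal -> distal for leg/torso
    segments and proximal -> distal for arm segments, so a hanging arm is
    -90 deg).
    """

    frame_rate: float
    timestamps: np.ndarray
    coords: np.ndarray
    inclinations_deg: dict[str, np.ndarray] = field(default_factory=dict)
    joint_names: tuple[str, ...] = LINKAGE_JOINTS
    #: full projected segment cloud (frames, 23, 2), for stick-figure plots
    segment_coords: np.ndarray | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        _check_timestamps(self.timestamps, self.frame_rate)
        expected = (self.timestamps.size, len(self.joint_names), 2)
        if self.coords.shape != expected:
            raise FormatError(
                f"linkage coords shape {self.coords.shape} != expected {expected}"
            )

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def joint(self, name: str) -> np.ndarray:
        """(frames, 2) trajectory of one linkage joint."""
        return self.coords[:, self.joint_names.index(name), :]

    def frame_coords(self, i: int) -> dict[str, np.ndarray]:
        """Mapping joint name -> (horizontal, vertical) for frame ``i``."""
        return {n: self.coords[i, k] for k, n in enumerate(self.joint_names)}
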