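"""Shared per-frame scoring machinery for the RULA and REBA modules.

This module owns:

* the angle -> region mapping (which joint-angle channels feed which scoring
  region, and how boolean posture cues are derived from them), and
* the :class:`ErgoScoreSeries` container with its summary/argmax helpers.

Spine regions are scored on summed joint angles: trunk flexion is the sum of
the four lumbar/thoracic joint flexions, neck flexion the sum of the two
cervical joints — the regional angle an observer would judge from video.
Left and right upper limbs are scored separately; the frame's reported
result is the worse side (ties go to the right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AngleValidationError, EmptyInputError, FrameError
from .series import JointAngleSeries

TRUNK_JOINTS = ("jL5S1", "jL4L3", "jL1T12", "jT9T8")
NECK_JOINTS = ("jT1C7", "jC1Head")


@dataclass
class SidePosture:
    """One upper limb's (plus knee's) scoring inputs, degrees."""

    upper_arm_flexion: float
    shoulder_abduction: float
    shoulder_rotation: float
    shoulder_elevation: float
    elbow_flexion: float
    wrist_flexion: float
    wrist_deviation: float
    wrist_rotation: float
    knee_flexion: float


@dataclass
class PostureFrame:
    """All region angles and cue inputs for one frame."""

    trunk_flexion: float
    trunk_twist: float
    trunk_side_bend: float
    neck_flexion: float
    neck_twist: float
    neck_side_bend: float
    right: SidePosture
    left: SidePosture

    def side(self, which: str) -> SidePosture:
        return self.right if which == "right" else self.left


def _side_posture(series: JointAngleSeries, i: int, side: str) -> SidePosture:
    s = side.capitalize()
    a = series.angles[i]
    j = {name: k for k, name in enumerate(series.joint_names)}
    return SidePosture(
        upper_arm_flexion=a[j[f"j{s}Shoulder"], 0],
        shoulder_abduction=a[j[f"j{s}Shoulder"], 1],
        shoulder_rotation=a[j[f"j{s}Shoulder"], 2],
        shoulder_elevation=a[j[f"j{s}C7Shoulder"], 1],
        elbow_flexion=a[j[f"j{s}Elbow"], 0],
        wrist_flexion=a[j[f"j{s}Wrist"], 0],
        wrist_deviation=a[j[f"j{s}Wrist"], 1],
        wrist_rotation=a[j[f"j{s}Wrist"], 2],
        knee_flexion=a[j[f"j{s}Knee"], 0],
    )


def extract_posture(series: JointAngleSeries, i: int) -> PostureFrame:
    """Build the scoring inputs for frame ``i`` from the 22-joint angles."""
    a = series.angles[i]
    j = {name: k for k, name in enumerate(series.joint_names)}
    trunk = [a[j[name]] for name in TRUNK_JOINTS]
    neck = [a[j[name]] for name in NECK_JOINTS]
    frame = PostureFrame(
        trunk_flexion=float(sum(t[0] for t in trunk)),
        trunk_twist=float(sum(t[2] for t in trunk)),
        trunk_side_bend=float(sum(t[1] for t in trunk)),
        neck_flexion=float(sum(t[0] for t in neck)),
        neck_twist=float(sum(t[2] for t in neck)),
        neck_side_bend=float(sum(t[1] for t in neck)),
        right=_side_posture(series, i, "right"),
        left=_side_posture(series, i, "left"),
    )
    for label, value in (
        ("trunk flexion", frame.trunk_flexion),
        ("neck flexion", frame.neck_flexion),
        ("right upper-arm flexion", frame.right.upper_arm_flexion),
        ("left upper-arm flexion", frame.left.upper_arm_flexion),
        ("right elbow flexion", frame.right.elbow_flexion),
        ("left elbow flexion", frame.left.elbow_flexion),
        ("right wrist flexion", frame.right.wrist_flexion),
        ("left wrist flexion", frame.left.wrist_flexion),
    ):
        if abs(value) > 180.0:
            raise AngleValidationError(
                f"{label} = {value:.1f} deg is outside physiological bounds"
            )
    return frame


@dataclass
class ErgoScoreSeries:
    """Per-frame postural scores for one method (RULA or REBA).

    ``frames`` holds one row per frame with the region scores, intermediate
    table scores, grand score and risk level.
    """

    method: str
    frame_rate: float
    frames: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def grand(self) -> np.ndarray:
        return self.frames["grand"].to_numpy()

    @property
    def risk_level(self) -> pd.Series:
        return self.frames["risk_level"]


def summarize(scores: ErgoScoreSeries) -> dict:
    """Average grand score, task duration, and score/risk distributions.

    Distribution values are proportions of frames and sum to 1.
    """
    if scores.n_frames == 0:
        raise EmptyInputError("cannot summarize an empty score series")
    grand = scores.grand
    n = scores.n_frames
    grand_dist = {
        int(s): c / n for s, c in zip(*np.unique(grand, return_counts=True))
    }
    risk_counts = scores.risk_level.value_counts()
    risk_dist = {level: c / n for level, c in risk_counts.items()}
    return {
        "method": scores.method,
        "average_grand": float(grand.mean()),
        "duration_s": n / scores.frame_rate,
        "grand_distribution": grand_dist,
        "risk_distribution": risk_dist,
        "max_frame": find_max(scores),
        "max_grand": int(grand.max()),
    }


def find_max(scores: ErgoScoreSeries) -> int:
    """Earliest frame index attaining the maximal grand score."""
    if scores.n_frames == 0:
        raise EmptyInputError("cannot find the maximum of an empty score series")
    return int(np.argmax(scores.grand))


def score_series_frames(series: JointAngleSeries, frame_scorer) -> pd.DataFrame:
    """Apply a per-frame scorer over a series, annotating failures with the
    frame index.  ``frame_scorer(posture_frame) -> dict`` of row values."""
    if series.n_frames == 0:  # defensive; the container already forbids this
        raise EmptyInputError("empty joint-angle series")
    rows = []
    for i in range(series.n_frames):
        try:
            row = frame_scorer(extract_posture(series, i))
        except Exception as exc:  # annotate and re-raise
            raise FrameError(i, exc) from exc
        row["frame"] = i
        row["time"] = float(series.timestamps[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["frame", "time"]
    return df[lead + [c for c in df.columns if c not in lead]]
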