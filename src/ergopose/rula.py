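"""Automated RULA scoring.

RULA (Rapid Upper Limb Assessment) scores a working posture region by
region — upper arm, lower arm, wrist, wrist twist on the arm side; neck,
trunk, legs on the body side — bins each region's joint angle against
published thresholds, combines the region scores through look-up tables A
and B, adds muscle-use and force/load scores to form scores C and D, and
reads the grand score (1-7) from table C.  The grand score maps to an
ordinal WMSD risk level: negligible (1-2), low (3-4), medium (5-6),
high (7).

All thresholds and tables live in ``data/rula_tables.yaml`` (versioned,
documented schema).  Both upper limbs are scored; each frame reports the
worse side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .context import TaskContext
from .scoring import (
    ErgoScoreSeries,
    PostureFrame,
    SidePosture,
    find_max,
    score_series_frames,
    summarize,
)
from .series import JointAngleSeries
from .tables import ScoringTables, load_tables

__all__ = [
    "rula_region_scores",
    "rula_grand",
    "score_series",
    "summarize",
    "find_max",
    "RulaFrameResult",
]


@dataclass
class RulaFrameResult:
    """Scores for one frame (the reported, worse side)."""

    side: str
    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int
    score_a: int
    score_b: int
    muscle_score: int
    force_score: int
    score_c: int
    score_d: int
    grand: int
    risk_level: str


def _force_score(tables: ScoringTables, context: TaskContext) -> int:
    if context.shock_or_rapid_buildup:
        return int(tables.raw["shock_score"])
    sustained = context.muscle_use_static
    for band in tables.raw["force_bands"]:
        if band["min_kg"] <= context.load_kg < band["max_kg"]:
            return int(band["sustained"] if sustained else band["intermittent"])
    raise AssertionError("force bands must cover [0, inf)")  # pragma: no cover


def rula_region_scores(
    posture: PostureFrame,
    context: TaskContext,
    side: str = "right",
    tables: ScoringTables | None = None,
) -> dict[str, int]:
    """Region scores for one side of one frame.

    Angle bins and adjustment increments follow the RULA worksheet: e.g. the
    upper arm scores its flexion bin, +1 if the shoulder is raised, +1 if
    the arm is abducted, -1 if the arm is supported (floored at 1).
    """
    t = tables or load_tables("rula")
    cues = t.cues
    s: SidePosture = posture.side(side)

    upper_arm = t.bin("upper_arm", s.upper_arm_flexion)
    if abs(s.shoulder_elevation) > cues["shoulder_raised_deg"]:
        upper_arm += 1
    if abs(s.shoulder_abduction) > cues["shoulder_abduction_deg"]:
        upper_arm += 1
    if context.arm_supported:
        upper_arm = max(1, upper_arm - 1)

    lower_arm = t.bin("lower_arm", s.elbow_flexion)
    if abs(s.shoulder_rotation) > cues["arm_midline_rotation_deg"]:
        lower_arm += 1

    wrist = t.bin("wrist", s.wrist_flexion)
    if abs(s.wrist_deviation) > cues["wrist_deviation_deg"]:
        wrist += 1

    wrist_twist = 2 if abs(s.wrist_rotation) > cues["wrist_twist_end_range_deg"] else 1

    neck = t.bin("neck", posture.neck_flexion)
    if abs(posture.neck_twist) > cues["twist_deg"]:
        neck += 1
    if abs(posture.neck_side_bend) > cues["side_bend_deg"]:
        neck += 1

    trunk = t.bin("trunk", posture.trunk_flexion)
    if abs(posture.trunk_twist) > cues["twist_deg"]:
        trunk += 1
    if abs(posture.trunk_side_bend) > cues["side_bend_deg"]:
        trunk += 1

    legs = 1 if context.legs_supported else 2

    return {
        "upper_arm": upper_arm,
        "lower_arm": lower_arm,
        "wrist": wrist,
        "wrist_twist": wrist_twist,
        "neck": neck,
        "trunk": trunk,
        "legs": legs,
    }


def rula_grand(
    regions: dict[str, int],
    context: TaskContext,
    side: str = "right",
    tables: ScoringTables | None = None,
) -> RulaFrameResult:
    """Chain the look-up tables: A/B posture scores, + muscle-use and force
    scores -> C/D, grand from table C, risk level from the band map.

    Region scores outside a table's domain raise
    :class:`~ergopose.errors.TableLookupError` — they are never clamped.
    (The published 8+/7+ saturation rows of table C are part of RULA itself
    and are applied.)
    """
    t = tables or load_tables("rula")
    score_a = t._lookup(
        t.raw["table_a"],
        (regions["upper_arm"], regions["lower_arm"], regions["wrist"], regions["wrist_twist"]),
        "RULA table A",
    )
    score_b = t._lookup(
        t.raw["table_b"],
        (regions["neck"], regions["trunk"], regions["legs"]),
        "RULA table B",
    )
    muscle = 1 if context.muscle_use_static else 0
    force = _force_score(t, context)
    score_c = score_a + muscle + force
    score_d = score_b + muscle + force
    grand = t._lookup(
        t.raw["table_c"], (min(score_c, 8), min(score_d, 7)), "RULA table C"
    )
    return RulaFrameResult(
        side=side,
        **regions,
        score_a=score_a,
        score_b=score_b,
        muscle_score=muscle,
        force_score=force,
        score_c=score_c,
        score_d=score_d,
        grand=grand,
        risk_level=t.risk_level(grand),
    )


def score_frame(
    posture: PostureFrame, context: TaskContext, tables: ScoringTables | None = None
) -> RulaFrameResult:
    """Score both sides of one frame and return the worse (ties: right)."""
    t = tables or load_tables("rula")
    best = None
    for side in ("right", "left"):
        res = rula_grand(rula_region_scores(posture, context, side, t), context, side, t)
        if best is None or res.grand > best.grand:
            best = res
    return best


def score_series(series: JointAngleSeries, context: TaskContext) -> ErgoScoreSeries:
    """Score every frame of a joint-angle series; deterministic in inputs."""
    t = load_tables("rula")
    frames = score_series_frames(
        series, lambda posture: vars(score_frame(posture, context, t)).copy()
    )
    return ErgoScoreSeries(method="RULA", frame_rate=series.frame_rate, frames=frames)
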