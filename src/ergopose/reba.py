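"""Automated REBA scoring.

REBA (Rapid Entire Body Assessment) follows the same per-frame architecture
as RULA with whole-body emphasis: trunk/neck/legs feed table A (plus a load
score), upper arm/lower arm/wrist feed table B (plus a coupling score),
table C combines them, and an activity score (+1 per activity flag) yields
the grand score (1-15).  Risk levels: negligible (1), low (2-3),
medium (4-7), high (8-10), very high (11-15).

Tables and thresholds live in ``data/reba_tables.yaml``.  Both upper limbs
are scored; each frame reports the worse side.
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
    "reba_region_scores",
    "reba_grand",
    "score_series",
    "summarize",
    "find_max",
    "RebaFrameResult",
]


@dataclass
class RebaFrameResult:
    side: str
    trunk: int
    neck: int
    legs: int
    upper_arm: int
    lower_arm: int
    wrist: int
    load_score: int
    coupling_score: int
    activity_score: int
    score_a: int
    score_b: int
    score_c: int
    grand: int
    risk_level: str


def _load_score(tables: ScoringTables, context: TaskContext) -> int:
    raw = tables.raw
    load = context.load_kg
    score = None
    # the middle band is closed above (a 10 kg load scores 1, not 2)
    for band in raw["load_bands"]:
        if band["min_kg"] <= load < band["max_kg"] or (
            load == raw["load_max_kg_inclusive"] == band["max_kg"]
        ):
            score = int(band["score"])
            break
    if score is None:  # load above the last closed band
        score = int(raw["load_bands"][-1]["score"])
    if context.shock_or_rapid_buildup:
        score += int(raw["shock_increment"])
    return score


def reba_region_scores(
    posture: PostureFrame,
    context: TaskContext,
    side: str = "right",
    tables: ScoringTables | None = None,
) -> dict[str, int]:
    """Region scores per the REBA worksheet bins and adjustments."""
    t = tables or load_tables("reba")
    cues = t.cues
    s: SidePosture = posture.side(side)

    trunk = t.bin("trunk", posture.trunk_flexion)
    if (
        abs(posture.trunk_twist) > cues["twist_deg"]
        or abs(posture.trunk_side_bend) > cues["side_bend_deg"]
    ):
        trunk += 1

    neck = t.bin("neck", posture.neck_flexion)
    if (
        abs(posture.neck_twist) > cues["twist_deg"]
        or abs(posture.neck_side_bend) > cues["side_bend_deg"]
    ):
        neck += 1

    legs = 1 if context.legs_supported else 2
    knee = max(abs(posture.right.knee_flexion), abs(posture.left.knee_flexion))
    legs += t.bin("knee_increment", knee)

    upper_arm = t.bin("upper_arm", s.upper_arm_flexion)
    if (
        abs(s.shoulder_abduction) > cues["shoulder_abduction_deg"]
        or abs(s.shoulder_rotation) > cues["arm_rotation_deg"]
    ):
        upper_arm += 1
    if abs(s.shoulder_elevation) > cues["shoulder_raised_deg"]:
        upper_arm += 1
    if context.arm_supported:
        upper_arm = max(1, upper_arm - 1)

    lower_arm = t.bin("lower_arm", s.elbow_flexion)

    wrist = t.bin("wrist", s.wrist_flexion)
    if (
        abs(s.wrist_deviation) > cues["wrist_deviation_deg"]
        or abs(s.wrist_rotation) > cues["wrist_twist_deg"]
    ):
        wrist += 1

    return {
        "trunk": trunk,
        "neck": neck,
        "legs": legs,
        "upper_arm": upper_arm,
        "lower_arm": lower_arm,
        "wrist": wrist,
    }


def reba_grand(
    regions: dict[str, int],
    context: TaskContext,
    side: str = "right",
    tables: ScoringTables | None = None,
) -> RebaFrameResult:
    """Table A + load -> score A; table B + coupling -> score B; table C;
    + activity score -> grand; risk level from the band map."""
    t = tables or load_tables("reba")
    base_a = t._lookup(
        t.raw["table_a"], (regions["neck"], regions["trunk"], regions["legs"]),
        "REBA table A",
    )
    base_b = t._lookup(
        t.raw["table_b"],
        (regions["lower_arm"], regions["upper_arm"], regions["wrist"]),
        "REBA table B",
    )
    load = _load_score(t, context)
    coupling = int(t.raw["coupling_scores"][context.coupling])
    score_a = base_a + load
    score_b = base_b + coupling
    score_c = t._lookup(
        t.raw["table_c"], (min(score_a, 12), min(score_b, 12)), "REBA table C"
    )
    activity = sum(
        (
            context.activity_static_hold,
            context.activity_repeated,
            context.activity_rapid_change,
        )
    )
    grand = score_c + activity
    return RebaFrameResult(
        side=side,
        **regions,
        load_score=load,
        coupling_score=coupling,
        activity_score=activity,
        score_a=score_a,
        score_b=score_b,
        score_c=score_c,
        grand=grand,
        risk_level=t.risk_level(grand),
    )


def score_frame(
    posture: PostureFrame, context: TaskContext, tables: ScoringTables | None = None
) -> RebaFrameResult:
    """Score both sides of one frame and return the worse (ties: right)."""
    t = tables or load_tables("reba")
    best = None
    for side in ("right", "left"):
        res = reba_grand(reba_region_scores(posture, context, side, t), context, side, t)
        if best is None or res.grand > best.grand:
            best = res
    return best


def score_series(series: JointAngleSeries, context: TaskContext) -> ErgoScoreSeries:
    t = load_tables("reba")
    frames = score_series_frames(
        series, lambda posture: vars(score_frame(posture, context, t)).copy()
    )
    return ErgoScoreSeries(method="REBA", frame_rate=series.frame_rate, frames=frames)
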