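"""Synthetic kinematics for canonical work postures.

Generates mutually coherent joint-angle and segment-position time series for
constant postures (plus Gaussian angle noise) and for multi-posture task
cycles, over a skeleton scaled with the same anthropometric length fractions
the biomechanics module uses.  Postures emulate canonical industrial work
shapes — neutral standing, stooped lifting with graded trunk flexion and
twisting, overhead work, wall painting — and the named battery postures
carry frozen oracle RULA/REBA labels derived from an independent
transcription of the scoring worksheets, never from this package's scoring
code, so the scoring modules can be tested end to end.

Conventions: sagittal plane = global XZ (X forward, Z up, Y left); angles
in degrees; a fixed seed fixes the full output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .anthro import Anthropometry, default_anthropometry
from .body import JOINTS, SEGMENTS
from .context import TaskContext
from .errors import GenerationError
from .series import JointAngleSeries, SegmentPositionSeries

#: Angle fields of a posture spec, interpolated during task cycles.
_ANGLE_FIELDS = (
    "trunk_flexion", "trunk_twist", "trunk_side_bend",
    "neck_flexion", "neck_twist", "neck_side_bend",
    "shoulder_flexion", "shoulder_abduction", "shoulder_rotation",
    "shoulder_elevation", "elbow_flexion",
    "wrist_flexion", "wrist_deviation", "wrist_rotation",
    "knee_flexion", "ankle_lean",
)

TRUNK_JOINTS = ("jL5S1", "jL4L3", "jL1T12", "jT9T8")
NECK_JOINTS = ("jT1C7", "jC1Head")


@dataclass
class PostureSpec:
    """A constant work posture plus its task context and sampling settings.

    Region angles are degrees (flexion positive, extension negative);
    shoulder/elbow/wrist angles apply to both arms symmetrically.
    """

    name: str = "custom"
    trunk_flexion: float = 0.0
    trunk_twist: float = 0.0
    trunk_side_bend: float = 0.0
    neck_flexion: float = 0.0
    neck_twist: float = 0.0
    neck_side_bend: float = 0.0
    shoulder_flexion: float = 0.0
    shoulder_abduction: float = 0.0
    shoulder_rotation: float = 0.0
    shoulder_elevation: float = 0.0
    elbow_flexion: float = 0.0
    wrist_flexion: float = 0.0
    wrist_deviation: float = 0.0
    wrist_rotation: float = 0.0
    knee_flexion: float = 0.0
    ankle_lean: float = 0.0
    load_kg: float = 0.0
    coupling: str = "good"
    muscle_use_static: bool = False
    shock_or_rapid_buildup: bool = False
    arm_supported: bool = False
    legs_supported: bool = True
    activity_static_hold: bool = False
    activity_repeated: bool = False
    activity_rapid_change: bool = False
    subject_mass_kg: float = 68.4
    subject_height_m: float = 1.731
    duration_s: float = 1.0
    frame_rate_hz: float = 20.0
    noise_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate_hz <= 0:
            raise GenerationError("frame rate must be positive")
        if self.noise_sd_deg < 0:
            raise GenerationError("noise SD must be >= 0")
        if self.duration_s <= 0:
            raise GenerationError("duration must be positive")

    def context(self) -> TaskContext:
        return TaskContext(
            load_kg=self.load_kg,
            coupling=self.coupling,
            muscle_use_static=self.muscle_use_static,
            shock_or_rapid_buildup=self.shock_or_rapid_buildup,
            arm_supported=self.arm_supported,
            legs_supported=self.legs_supported,
            activity_static_hold=self.activity_static_hold,
            activity_repeated=self.activity_repeated,
            activity_rapid_change=self.activity_rapid_change,
            subject_mass_kg=self.subject_mass_kg,
            subject_height_m=self.subject_height_m,
        )

    def angle_values(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in _ANGLE_FIELDS}


@dataclass
class OracleLabel:
    """Expected zero-noise scores for a battery posture.

    Derived offline from an independent transcription of the RULA/REBA
    worksheets and look-up tables (the same transcription the test suite
    uses as its brute-force oracle) — never from the scoring modules.
    """

    rula_grand: int
    rula_risk: str
    reba_grand: int
    reba_risk: str


# ---------------------------------------------------------------------------
# forward kinematics


def _skeleton_positions(angles: dict[str, float], anthro: Anthropometry) -> np.ndarray:
    """3D positions (23 x 3) of all segment origins for one set of region
    angles, by planar forward kinematics plus axial twist/side-bend of the
    upper body about L5/S1."""
    s = anthro.stature_m
    L = {seg: anthro.length(seg) for seg in
         ("shank", "thigh", "pelvis", "trunk_upper", "upper_arm", "forearm",
          "hand", "head_neck")}
    w_hip, w_shoulder = 0.052 * s, 0.10 * s
    rad = math.radians

    a_shank = rad(angles["ankle_lean"] + angles["knee_flexion"] / 3.0)
    a_thigh = a_shank - rad(angles["knee_flexion"])
    a_trunk = rad(angles["trunk_flexion"])
    alpha = a_trunk + rad(angles["shoulder_flexion"])  # upper arm, from vertical-down
    beta = rad(angles["shoulder_abduction"])
    a_fore = alpha + rad(angles["elbow_flexion"])
    a_neck = a_trunk + rad(angles["neck_flexion"])

    ankle = np.array([0.0, 0.0, 0.039 * s])
    knee = ankle + L["shank"] * np.array([math.sin(a_shank), 0, math.cos(a_shank)])
    hip = knee + L["thigh"] * np.array([math.sin(a_thigh), 0, math.cos(a_thigh)])
    trunk_dir = np.array([math.sin(a_trunk), 0, math.cos(a_trunk)])
    l5s1 = hip + L["pelvis"] * trunk_dir
    c7 = l5s1 + L["trunk_upper"] * trunk_dir
    head = c7 + 0.5 * L["head_neck"] * np.array([math.sin(a_neck), 0, math.cos(a_neck)])

    def arm(side_sign: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        origin = c7 + np.array([0.0, side_sign * w_shoulder, 0.0])
        u = np.array([
            math.sin(alpha) * math.cos(beta),
            side_sign * math.sin(beta),
            -math.cos(alpha) * math.cos(beta),
        ])
        v = np.array([
            math.sin(a_fore) * math.cos(beta),
            side_sign * math.sin(beta),
            -math.cos(a_fore) * math.cos(beta),
        ])
        elbow = origin + L["upper_arm"] * u
        wrist = elbow + L["forearm"] * v
        return origin, elbow, wrist

    # Y is left: right side is -1
    r_org, r_elb, r_wri = arm(-1.0)
    l_org, l_elb, l_wri = arm(+1.0)

    pos = {
        "Pelvis": hip.copy(),
        "L5": l5s1,
        "L3": l5s1 + 0.25 * (c7 - l5s1),
        "T12": l5s1 + 0.50 * (c7 - l5s1),
        "T8": l5s1 + 0.75 * (c7 - l5s1),
        "Neck": c7,
        "Head": head,
        "RightShoulder": c7 + np.array([0.0, -0.5 * w_shoulder, 0.0]),
        "RightUpperArm": r_org, "RightForeArm": r_elb, "RightHand": r_wri,
        "LeftShoulder": c7 + np.array([0.0, 0.5 * w_shoulder, 0.0]),
        "LeftUpperArm": l_org, "LeftForeArm": l_elb, "LeftHand": l_wri,
        "RightUpperLeg": hip + np.array([0.0, -w_hip, 0.0]),
        "RightLowerLeg": knee + np.array([0.0, -w_hip, 0.0]),
        "RightFoot": ankle + np.array([0.0, -w_hip, 0.0]),
        "RightToe": ankle + np.array([0.12, -w_hip, -0.02]),
        "LeftUpperLeg": hip + np.array([0.0, w_hip, 0.0]),
        "LeftLowerLeg": knee + np.array([0.0, w_hip, 0.0]),
        "LeftFoot": ankle + np.array([0.0, w_hip, 0.0]),
        "LeftToe": ankle + np.array([0.12, w_hip, -0.02]),
    }

    # axial twist and lateral bend of everything above L5/S1, about L5/S1
    tau = rad(angles["trunk_twist"])
    sigma = rad(angles["trunk_side_bend"])
    if tau or sigma:
        above = ("L3", "T12", "T8", "Neck", "Head",
                 "RightShoulder", "RightUpperArm", "RightForeArm", "RightHand",
                 "LeftShoulder", "LeftUpperArm", "LeftForeArm", "LeftHand")
        ct, st = math.cos(tau), math.sin(tau)
        cs, ss = math.cos(sigma), math.sin(sigma)
        for segname in above:
            d = pos[segname] - l5s1
            # side-bend: rotation about the forward (X) axis
            d = np.array([d[0], d[1] * cs - d[2] * ss, d[1] * ss + d[2] * cs])
            # twist: rotation about the vertical (Z) axis
            d = np.array([d[0] * ct - d[1] * st, d[0] * st + d[1] * ct, d[2]])
            pos[segname] = l5s1 + d

    arr = np.array([pos[seg] for seg in SEGMENTS])
    if np.any(arr[:, 2] < -0.005):
        raise GenerationError(
            f"posture drives body segments below the ground plane "
            f"(min height {arr[:, 2].min():.3f} m)"
        )
    return arr


def _hip_flexion_deg(angles: dict[str, float]) -> float:
    a_shank = angles["ankle_lean"] + angles["knee_flexion"] / 3.0
    a_thigh = a_shank - angles["knee_flexion"]
    return angles["trunk_flexion"] - a_thigh


def _angle_frame(angles: dict[str, float]) -> np.ndarray:
    """Canonical (22 x 3) joint-angle array for one set of region angles."""
    out = np.zeros((22, 3))
    j = {name: k for k, name in enumerate(JOINTS)}
    for joint in TRUNK_JOINTS:
        out[j[joint]] = (
            angles["trunk_flexion"] / 4.0,
            angles["trunk_side_bend"] / 4.0,
            angles["trunk_twist"] / 4.0,
        )
    for joint in NECK_JOINTS:
        out[j[joint]] = (
            angles["neck_flexion"] / 2.0,
            angles["neck_side_bend"] / 2.0,
            angles["neck_twist"] / 2.0,
        )
    hip = _hip_flexion_deg(angles)
    for side in ("Right", "Left"):
        out[j[f"j{side}Shoulder"]] = (
            angles["shoulder_flexion"],
            angles["shoulder_abduction"],
            angles["shoulder_rotation"],
        )
        out[j[f"j{side}C7Shoulder"], 1] = angles["shoulder_elevation"]
        out[j[f"j{side}Elbow"], 0] = angles["elbow_flexion"]
        out[j[f"j{side}Wrist"]] = (
            angles["wrist_flexion"],
            angles["wrist_deviation"],
            angles["wrist_rotation"],
        )
        out[j[f"j{side}Hip"], 0] = hip
        out[j[f"j{side}Knee"], 0] = angles["knee_flexion"]
        out[j[f"j{side}Ankle"], 0] = angles["ankle_lean"]
    return out


def _region_angles_from_frame(frame: np.ndarray) -> dict[str, float]:
    """Invert :func:`_angle_frame` (right side) for noisy per-frame FK."""
    j = {name: k for k, name in enumerate(JOINTS)}
    return {
        "trunk_flexion": float(sum(frame[j[t], 0] for t in TRUNK_JOINTS)),
        "trunk_side_bend": float(sum(frame[j[t], 1] for t in TRUNK_JOINTS)),
        "trunk_twist": float(sum(frame[j[t], 2] for t in TRUNK_JOINTS)),
        "neck_flexion": float(sum(frame[j[t], 0] for t in NECK_JOINTS)),
        "neck_side_bend": float(sum(frame[j[t], 1] for t in NECK_JOINTS)),
        "neck_twist": float(sum(frame[j[t], 2] for t in NECK_JOINTS)),
        "shoulder_flexion": float(frame[j["jRightShoulder"], 0]),
        "shoulder_abduction": float(frame[j["jRightShoulder"], 1]),
        "shoulder_rotation": float(frame[j["jRightShoulder"], 2]),
        "shoulder_elevation": float(frame[j["jRightC7Shoulder"], 1]),
        "elbow_flexion": float(frame[j["jRightElbow"], 0]),
        "wrist_flexion": float(frame[j["jRightWrist"], 0]),
        "wrist_deviation": float(frame[j["jRightWrist"], 1]),
        "wrist_rotation": float(frame[j["jRightWrist"], 2]),
        "knee_flexion": float(frame[j["jRightKnee"], 0]),
        "ankle_lean": float(frame[j["jRightAnkle"], 0]),
    }


def _series_from_angle_frames(
    frames: np.ndarray, frame_rate: float, anthro: Anthropometry
) -> tuple[JointAngleSeries, SegmentPositionSeries]:
    n = frames.shape[0]
    t = np.arange(n) / frame_rate
    angle_series = JointAngleSeries(frame_rate=frame_rate, timestamps=t, angles=frames)
    positions = np.empty((n, 23, 3))
    for i in range(n):
        positions[i] = _skeleton_positions(_region_angles_from_frame(frames[i]), anthro)
    position_series = SegmentPositionSeries(
        frame_rate=frame_rate, timestamps=t.copy(), positions=positions,
        up_axis="z", forward_axis="x",
    )
    return angle_series, position_series


def generate_posture_series(
    spec: PostureSpec,
) -> tuple[JointAngleSeries, SegmentPositionSeries, OracleLabel | None]:
    """Constant posture + Gaussian angle noise; positions by per-frame
    forward kinematics over the scaled skeleton.  Reproducible per seed.

    Returns the frozen oracle label when ``spec.name`` is a battery posture
    generated unmodified, else ``None``.
    """
    anthro = default_anthropometry(spec.subject_mass_kg, spec.subject_height_m)
    n = max(1, round(spec.duration_s * spec.frame_rate_hz))
    base = _angle_frame(spec.angle_values())
    frames = np.broadcast_to(base, (n, 22, 3)).copy()
    if spec.noise_sd_deg > 0:
        rng = np.random.default_rng(spec.seed)
        frames += rng.normal(0.0, spec.noise_sd_deg, size=frames.shape)
    # the spec must be realisable before we hand the series out
    _skeleton_positions(spec.angle_values(), anthro)
    angle_series, position_series = _series_from_angle_frames(
        frames, spec.frame_rate_hz, anthro
    )
    label = _battery_label(spec)
    return angle_series, position_series, label


def generate_task_cycle(
    keyframes: list[PostureSpec], transition_s: float
) -> tuple[JointAngleSeries, SegmentPositionSeries]:
    """Interpolate a cycle through posture keyframes.

    Each keyframe is held for its own ``duration_s``; between consecutive
    keyframes the region angles ramp along a smoothstep (monotone) profile
    over ``transition_s``.  Context, sampling and noise settings come from
    the first keyframe.
    """
    if len(keyframes) < 2:
        raise GenerationError("a task cycle needs at least 2 keyframes")
    if transition_s <= 0:
        raise GenerationError("transition duration must be positive")
    first = keyframes[0]
    rate = first.frame_rate_hz
    anthro = default_anthropometry(first.subject_mass_kg, first.subject_height_m)

    tracks = []  # per-frame region-angle dicts
    for k, spec in enumerate(keyframes):
        hold = max(1, round(spec.duration_s * rate))
        tracks.extend([spec.angle_values()] * hold)
        if k + 1 < len(keyframes):
            nxt = keyframes[k + 1].angle_values()
            cur = spec.angle_values()
            steps = max(1, round(transition_s * rate))
            for step in range(1, steps + 1):
                x = step / (steps + 1)
                w = x * x * (3 - 2 * x)  # smoothstep: monotone between targets
                tracks.append(
                    {f: (1 - w) * cur[f] + w * nxt[f] for f in _ANGLE_FIELDS}
                )
    frames = np.stack([_angle_frame(a) for a in tracks])
    if first.noise_sd_deg > 0:
        rng = np.random.default_rng(first.seed)
        frames = frames + rng.normal(0.0, first.noise_sd_deg, size=frames.shape)
    return _series_from_angle_frames(frames, rate, anthro)


def expected_inclinations(spec: PostureSpec) -> dict[str, float]:
    """Closed-form sagittal inclinations (degrees from horizontal) implied
    by a posture spec, for consistency checks against projected positions."""
    a_shank = spec.ankle_lean + spec.knee_flexion / 3.0
    a_thigh = a_shank - spec.knee_flexion
    alpha = spec.trunk_flexion + spec.shoulder_flexion
    return {
        "shank": 90.0 - a_shank,
        "thigh": 90.0 - a_thigh,
        "pelvis": 90.0 - spec.trunk_flexion,
        "trunk": 90.0 - spec.trunk_flexion,
        "upper_arm": alpha - 90.0,
        "forearm": alpha + spec.elbow_flexion - 90.0,
    }


# ---------------------------------------------------------------------------
# battery of canonical work postures with frozen oracle labels

def _battery() -> dict[str, tuple[PostureSpec, OracleLabel]]:
    P = PostureSpec
    L = OracleLabel
    specs: list[tuple[PostureSpec, OracleLabel]] = [
        (P(name="neutral_standing"),
         L(2, "negligible", 1, "negligible")),
        (P(name="neutral_standing_5kg", load_kg=5.0),
         L(3, "low", 1, "negligible")),
        (P(name="slight_stoop", trunk_flexion=10.0, neck_flexion=5.0),
         L(2, "negligible", 1, "negligible")),
        (P(name="moderate_stoop", trunk_flexion=30.0, neck_flexion=15.0,
           shoulder_flexion=30.0, elbow_flexion=30.0),
         L(4, "low", 2, "low")),
        (P(name="stoop_lift_30deg_5kg", trunk_flexion=30.0, neck_flexion=15.0,
           shoulder_flexion=30.0, elbow_flexion=30.0, load_kg=5.0),
         L(5, "medium", 3, "low")),
        (P(name="stoop_lift_60deg", trunk_flexion=55.0, neck_flexion=20.0,
           shoulder_flexion=40.0, elbow_flexion=20.0, load_kg=5.0),
         L(5, "medium", 4, "medium")),
        (P(name="deep_stoop_lift_5kg", trunk_flexion=70.0, neck_flexion=25.0,
           shoulder_flexion=50.0, elbow_flexion=15.0, load_kg=5.0,
           wrist_flexion=10.0),
         L(7, "high", 7, "medium")),
        (P(name="deep_stoop_lift_twisted", trunk_flexion=70.0, trunk_twist=30.0,
           neck_flexion=25.0, shoulder_flexion=50.0, elbow_flexion=15.0,
           load_kg=5.0),
         L(6, "medium", 8, "high")),
        (P(name="stoop_twist_30deg", trunk_flexion=30.0, trunk_twist=30.0,
           neck_flexion=10.0, shoulder_flexion=25.0, elbow_flexion=70.0),
         L(4, "low", 2, "low")),
        (P(name="squat_lift_5kg", trunk_flexion=30.0, knee_flexion=75.0,
           shoulder_flexion=30.0, elbow_flexion=45.0, load_kg=5.0,
           legs_supported=True),
         L(4, "low", 6, "medium")),
        (P(name="semi_squat_lift", trunk_flexion=20.0, knee_flexion=45.0,
           shoulder_flexion=25.0, elbow_flexion=60.0, load_kg=5.0),
         L(4, "low", 4, "medium")),
        (P(name="overhead_work", trunk_flexion=-10.0, neck_flexion=-15.0,
           shoulder_flexion=120.0, elbow_flexion=30.0, wrist_flexion=10.0),
         L(5, "medium", 4, "medium")),
        (P(name="overhead_work_static", trunk_flexion=-10.0, neck_flexion=-15.0,
           shoulder_flexion=120.0, elbow_flexion=30.0,
           muscle_use_static=True, activity_static_hold=True),
         L(7, "high", 5, "medium")),
        (P(name="overhead_abducted", shoulder_flexion=100.0,
           shoulder_abduction=60.0, elbow_flexion=40.0, neck_flexion=-10.0),
         L(6, "medium", 4, "medium")),
        (P(name="wall_paint_horizontal", shoulder_flexion=70.0,
           elbow_flexion=40.0, wrist_flexion=20.0, wrist_deviation=20.0,
           activity_repeated=True),
         L(4, "low", 4, "medium")),
        (P(name="wall_paint_vertical", shoulder_flexion=50.0,
           elbow_flexion=80.0, wrist_flexion=-20.0, muscle_use_static=True,
           activity_repeated=True),
         L(4, "low", 3, "low")),
        (P(name="paint_sloped_wall", trunk_flexion=-12.0, neck_flexion=-10.0,
           shoulder_flexion=95.0, elbow_flexion=25.0, wrist_flexion=10.0),
         L(5, "medium", 4, "medium")),
        (P(name="welding_flat_bench", trunk_flexion=25.0, neck_flexion=22.0,
           shoulder_flexion=35.0, elbow_flexion=75.0, wrist_deviation=20.0,
           muscle_use_static=True, activity_static_hold=True),
         L(5, "medium", 5, "medium")),
        (P(name="welding_overhead", trunk_flexion=-8.0, neck_flexion=-12.0,
           shoulder_flexion=130.0, elbow_flexion=20.0, wrist_flexion=18.0,
           muscle_use_static=True, activity_static_hold=True),
         L(7, "high", 6, "medium")),
        (P(name="welding_vertical_crouch", trunk_flexion=15.0, neck_flexion=15.0,
           knee_flexion=65.0, shoulder_flexion=45.0, elbow_flexion=90.0,
           legs_supported=False, muscle_use_static=True),
         L(4, "low", 4, "medium")),
        (P(name="carry_12kg", trunk_flexion=8.0, shoulder_flexion=10.0,
           elbow_flexion=90.0, load_kg=12.0, coupling="fair"),
         L(5, "medium", 4, "medium")),
        (P(name="carry_12kg_poor_grip", trunk_flexion=8.0, shoulder_flexion=10.0,
           elbow_flexion=90.0, load_kg=12.0, coupling="poor",
           shock_or_rapid_buildup=True),
         L(5, "medium", 4, "medium")),
        (P(name="neck_extension_reach", neck_flexion=-15.0,
           shoulder_flexion=85.0, elbow_flexion=10.0),
         L(4, "low", 2, "low")),
        (P(name="elevated_shoulders_reach", shoulder_flexion=60.0,
           shoulder_elevation=25.0, elbow_flexion=20.0, wrist_rotation=70.0),
         L(3, "low", 3, "low")),
        (P(name="extreme_manual_handling", trunk_flexion=70.0,
           trunk_twist=30.0, trunk_side_bend=25.0, neck_flexion=25.0,
           neck_twist=30.0, shoulder_flexion=100.0, shoulder_abduction=60.0,
           shoulder_elevation=25.0, shoulder_rotation=70.0, elbow_flexion=20.0,
           wrist_flexion=20.0, wrist_deviation=20.0, wrist_rotation=70.0,
           knee_flexion=65.0, legs_supported=False, load_kg=12.0,
           coupling="unacceptable", muscle_use_static=True,
           shock_or_rapid_buildup=True, activity_static_hold=True,
           activity_repeated=True, activity_rapid_change=True),
         L(7, "high", 15, "very_high")),
    ]
    return {spec.name: (spec, label) for spec, label in specs}


_BATTERY_CACHE: dict[str, tuple[PostureSpec, OracleLabel]] | None = None


def posture_battery() -> dict[str, tuple[PostureSpec, OracleLabel]]:
    """Named canonical postures with frozen zero-noise oracle labels."""
    global _BATTERY_CACHE
    if _BATTERY_CACHE is None:
        _BATTERY_CACHE = _battery()
    return _BATTERY_CACHE


def get_posture(name: str, **overrides) -> PostureSpec:
    """Fetch a battery posture by name, optionally overriding sampling
    fields (noise, seed, duration...)."""
    spec, _ = posture_battery()[name]
    return replace(spec, **overrides) if overrides else spec


def _battery_label(spec: PostureSpec) -> OracleLabel | None:
    entry = posture_battery().get(spec.name)
    if entry is None:
        return None
    ref, label = entry
    # the label only applies if the scoring-relevant fields are unmodified
    relevant = _ANGLE_FIELDS + (
        "load_kg", "coupling", "muscle_use_static", "shock_or_rapid_buildup",
        "arm_supported", "legs_supported", "activity_static_hold",
        "activity_repeated", "activity_rapid_change",
    )
    if all(getattr(spec, f) == getattr(ref, f) for f in relevant):
        return label
    return None
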