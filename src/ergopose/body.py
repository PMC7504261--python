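"""The 22-joint / 23-segment body model and the canonical channel vocabulary.

The joint and segment inventory follows the layout used by full-body inertial
motion-capture suits: a 7-link axial chain (pelvis through head), two 4-link
arms and two 4-link legs.  Joint angles are expressed as three anatomical
components per joint — (flexion/extension, abduction/adduction,
internal/external rotation) — in degrees, flexion positive.  Segment
positions are the global 3D coordinates of each segment's proximal origin,
in metres.

Canonical channel names are ``<joint>_<component>`` (e.g.
``jRightShoulder_flexion``) and ``<segment>_<axis>`` (e.g. ``Pelvis_x``).
An alias table maps common mocap-export spellings onto the canonical names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Anatomical angle components, in canonical order.
COMPONENTS: tuple[str, str, str] = ("flexion", "abduction", "rotation")

#: Cartesian axes for segment positions, in canonical order.
AXES: tuple[str, str, str] = ("x", "y", "z")

#: The 22 skeletal joints, axial chain first, then right arm, left arm,
#: right leg, left leg.
JOINTS: tuple[str, ...] = (
    "jL5S1", "jL4L3", "jL1T12", "jT9T8", "jT1C7", "jC1Head",
    "jRightC7Shoulder", "jRightShoulder", "jRightElbow", "jRightWrist",
    "jLeftC7Shoulder", "jLeftShoulder", "jLeftElbow", "jLeftWrist",
    "jRightHip", "jRightKnee", "jRightAnkle", "jRightBallFoot",
    "jLeftHip", "jLeftKnee", "jLeftAnkle", "jLeftBallFoot",
)

#: The 23 body segments.
SEGMENTS: tuple[str, ...] = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForeArm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForeArm", "LeftHand",
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)

#: Kinematic tree: segment -> parent segment; the pelvis is the root.
PARENT_MAP: dict[str, str | None] = {
    "Pelvis": None,
    "L5": "Pelvis", "L3": "L5", "T12": "L3", "T8": "T12",
    "Neck": "T8", "Head": "Neck",
    "RightShoulder": "T8", "RightUpperArm": "RightShoulder",
    "RightForeArm": "RightUpperArm", "RightHand": "RightForeArm",
    "LeftShoulder": "T8", "LeftUpperArm": "LeftShoulder",
    "LeftForeArm": "LeftUpperArm", "LeftHand": "LeftForeArm",
    "RightUpperLeg": "Pelvis", "RightLowerLeg": "RightUpperLeg",
    "RightFoot": "RightLowerLeg", "RightToe": "RightFoot",
    "LeftUpperLeg": "Pelvis", "LeftLowerLeg": "LeftUpperLeg",
    "LeftFoot": "LeftLowerLeg", "LeftToe": "LeftFoot",
}


@dataclass(frozen=True)
class BodyModel:
    """Joint/segment inventory plus the kinematic tree.

    Invariants (checked on construction): exactly 22 joints, exactly 23
    segments, and ``parent_map`` forms a tree with a single root.
    """

    joint_names: tuple[str, ...] = JOINTS
    segment_names: tuple[str, ...] = SEGMENTS
    parent_map: dict[str, str | None] = field(default_factory=lambda: dict(PARENT_MAP))

    def __post_init__(self):
        if len(self.joint_names) != 22:
            raise ValueError(f"expected 22 joints, got {len(self.joint_names)}")
        if len(self.segment_names) != 23:
            raise ValueError(f"expected 23 segments, got {len(self.segment_names)}")
        roots = [s for s, p in self.parent_map.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"parent map must have exactly one root, got {roots}")
        # acyclicity: walking up from every segment must reach the root
        root = roots[0]
        for seg in self.segment_names:
            seen, cur = set(), seg
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in parent map at {cur!r}")
                seen.add(cur)
                cur = self.parent_map.get(cur)
            if root not in seen:
                raise ValueError(f"segment {seg!r} does not reach the root")

    @property
    def root(self) -> str:
        return next(s for s, p in self.parent_map.items() if p is None)


DEFAULT_BODY = BodyModel()

#: Canonical angle channels, one per joint x component (66 total).
ANGLE_CHANNELS: tuple[str, ...] = tuple(
    f"{j}_{c}" for j in JOINTS for c in COMPONENTS
)

#: Canonical position channels, one per segment x axis (69 total).
POSITION_CHANNELS: tuple[str, ...] = tuple(
    f"{s}_{a}" for s in SEGMENTS for a in AXES
)

# Alias table for common mocap export spellings.  Keys are matched after
# lower-casing and squeezing non-alphanumerics, so e.g.
# "Right Shoulder Flexion/Extension" and "right_shoulder_flexion_extension"
# both resolve to jRightShoulder_flexion.
_COMPONENT_ALIASES = {
    "flexion": "flexion", "flexionextension": "flexion", "fe": "flexion",
    "abduction": "abduction", "abductionadduction": "abduction",
    "lateralbending": "abduction", "aa": "abduction",
    "rotation": "rotation", "internalexternalrotation": "rotation",
    "axialrotation": "rotation", "pronationsupination": "rotation",
}


def _squeeze(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "", name.lower())


_CANONICAL_BY_SQUEEZED: dict[str, str] = {}
for _ch in ANGLE_CHANNELS + POSITION_CHANNELS + ("time",):
    _CANONICAL_BY_SQUEEZED[_squeeze(_ch)] = _ch
# joint names without the leading "j" are also accepted
for _j in JOINTS:
    for _c in COMPONENTS:
        _CANONICAL_BY_SQUEEZED[_squeeze(f"{_j[1:]}_{_c}")] = f"{_j}_{_c}"
        for _alias, _canon in _COMPONENT_ALIASES.items():
            if _canon == _c:
                _CANONICAL_BY_SQUEEZED[_squeeze(f"{_j}_{_alias}")] = f"{_j}_{_c}"
                _CANONICAL_BY_SQUEEZED[_squeeze(f"{_j[1:]}_{_alias}")] = f"{_j}_{_c}"


def canonical_channel(name: str) -> str | None:
    """Resolve a file column name to the canonical channel vocabulary.

    Returns ``None`` when the name matches nothing we know (such columns are
    ignored with a warning by the readers).
    """
    return _CANONICAL_BY_SQUEEZED.get(_squeeze(name))
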