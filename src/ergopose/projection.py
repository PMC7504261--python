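"""Sagittal-plane projection of 3D segment positions.

The 2D linkage model assumes symmetric activity in the sagittal plane, so the
3D segment cloud is flattened onto a vertical plane before any statics.  Two
plane definitions are supported:

* ``pelvis-heading`` (default) — the plane spanned by gravity and the
  subject's horizontal forward vector, derived per frame from the hip
  segment positions.  Correct for subjects who have turned away from the
  global axes.
* ``global-xz`` — the plane spanned by the declared forward and up axes of
  the file; fallback when the pelvis heading is degenerate or when the
  recording is known to be axis-aligned.

Projection keeps the in-plane horizontal component and the vertical
component and discards the lateral one, so projected distances never exceed
3D distances and projecting already-planar data is a no-op.
"""

from __future__ import annotations

import numpy as np

from .body import AXES, SEGMENTS
from .errors import ProjectionError
from .series import LINKAGE_JOINTS, LINKAGE_SEGMENTS, LinkageStateSeries, SegmentPositionSeries

#: How the 8 linkage joints are derived from the 23-segment cloud.  Each
#: entry is the list of segment origins to average (left/right midpoints).
LINKAGE_FROM_SEGMENTS: dict[str, tuple[str, ...]] = {
    "ankle": ("RightFoot", "LeftFoot"),
    "knee": ("RightLowerLeg", "LeftLowerLeg"),
    "hip": ("RightUpperLeg", "LeftUpperLeg"),
    "l5s1": ("L5",),
    "shoulder": ("RightUpperArm", "LeftUpperArm"),
    "elbow": ("RightForeArm", "LeftForeArm"),
    "wrist": ("RightHand", "LeftHand"),
}

#: The grip point ("hand" linkage joint) is the wrist extended along the
#: forearm direction by this fraction of the forearm vector — it lands near
#: the hand's centre of mass, where a hand-held load acts.
HAND_EXTENSION_RATIO = 0.37


def _axis_index(axis: str) -> int:
    return AXES.index(axis.lower())


def project_sagittal(
    positions: SegmentPositionSeries,
    plane_definition: str = "pelvis-heading",
) -> LinkageStateSeries:
    """Project a 3D segment-position series into the sagittal plane.

    Returns a :class:`LinkageStateSeries` with per-frame 2D coordinates
    (horizontal-in-plane, vertical) for the linkage joints, per-segment
    inclination angles, and the projected full segment cloud for plotting.

    Raises :class:`ProjectionError` when ``pelvis-heading`` is requested but
    the heading vector is degenerate (zero horizontal length).
    """
    if plane_definition not in ("pelvis-heading", "global-xz"):
        raise ValueError(f"unknown plane definition {plane_definition!r}")

    up = np.zeros(3)
    up[_axis_index(positions.up_axis)] = 1.0
    n, pos = positions.n_frames, positions.positions
    sindex = {s: i for i, s in enumerate(SEGMENTS)}

    if plane_definition == "global-xz":
        fwd = np.zeros(3)
        fwd[_axis_index(positions.forward_axis)] = 1.0
        forward = np.broadcast_to(fwd, (n, 3))
    else:
        # per-frame heading: horizontal forward = up x (left-hip -> right-hip)
        r = pos[:, sindex["RightUpperLeg"]] - pos[:, sindex["LeftUpperLeg"]]
        f = np.cross(np.broadcast_to(up, (n, 3)), r)
        f -= np.outer(f @ up, up)  # keep strictly horizontal
        norms = np.linalg.norm(f, axis=1)
        if np.any(norms < 1e-9):
            raise ProjectionError(
                "degenerate pelvis heading (coincident hip segments); "
                "use plane_definition='global-xz'"
            )
        forward = f / norms[:, None]

    # planar coordinates of the full segment cloud
    seg2d = np.empty((n, 23, 2))
    seg2d[:, :, 0] = np.einsum("fsa,fa->fs", pos, forward)
    seg2d[:, :, 1] = pos @ up

    coords = np.empty((n, len(LINKAGE_JOINTS), 2))
    for k, joint in enumerate(LINKAGE_JOINTS):
        if joint == "hand":
            continue
        members = [sindex[s] for s in LINKAGE_FROM_SEGMENTS[joint]]
        coords[:, k] = seg2d[:, members].mean(axis=1)
    iw = LINKAGE_JOINTS.index("wrist")
    ie = LINKAGE_JOINTS.index("elbow")
    coords[:, LINKAGE_JOINTS.index("hand")] = coords[:, iw] + HAND_EXTENSION_RATIO * (
        coords[:, iw] - coords[:, ie]
    )

    inclinations = {}
    jindex = {j: k for k, j in enumerate(LINKAGE_JOINTS)}
    for name, proximal, distal in LINKAGE_SEGMENTS:
        d = coords[:, jindex[distal]] - coords[:, jindex[proximal]]
        inclinations[name] = np.degrees(np.arctan2(d[:, 1], d[:, 0]))

    return LinkageStateSeries(
        frame_rate=positions.frame_rate,
        timestamps=positions.timestamps.copy(),
        coords=coords,
        inclinations_deg=inclinations,
        segment_coords=seg2d,
    )
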