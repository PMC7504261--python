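"""2D coplanar multiple-linkage static biomechanical analysis.

The model treats a symmetric sagittal-plane posture as a single chain of
rigid links — hand, forearm, upper arm, upper trunk (with the head/neck as
an attached point mass), pelvis link, thigh, shank — and propagates forces
and moments from the hand-held load down to the ankle by segment-wise
statics (zero acceleration).  At each linkage joint the reaction force is
the weight of everything distal plus the external load, and the net sagittal
moment is the sum of weight x horizontal-lever-arm terms about that joint.

At the L5/S1 disc the moment is balanced by the erector spinae (a single
equivalent extensor at moment arm E behind the disc) with relief from
intra-abdominal pressure acting on the diaphragm at moment arm D in front
of it:

    P_A  = c * max(0, 43 - 0.36*(theta_H + theta_T)) * |M|^1.8   [mmHg]
    F_A  = P_A * diaphragm area
    F_M  = max(0, (|M| - F_A * D) / E)
    F_C  = (W + L) * sin(theta_T') + F_M - F_A      (along the disc normal)
    F_S  = (W + L) * cos(theta_T')                  (transverse)

where theta_T / theta_H are the trunk and thigh inclinations from the
horizontal (degrees), theta_T' the trunk inclination, W the superincumbent
body weight and L the load weight.  This is the classic
occupational-biomechanics formulation of the abdominal-pressure relief
mechanism; all constants are configurable and the whole pressure model is
pluggable.

Strength percent capable treats population static strength at each joint as
Gaussian with the configured mean/SD per moment direction:
``% = Phi((mean - |M|)/SD) * 100`` — the share of the population able to
produce the demanded moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .anthro import Anthropometry
from .context import TaskContext
from .errors import (
    ConfigurationError,
    CoverageError,
    EmptyInputError,
    FrameError,
    ModelIncompleteError,
)
from .projection import project_sagittal
from .series import LINKAGE_JOINTS, LinkageStateSeries, SegmentPositionSeries

G = 9.80665  # m/s^2

MMHG_TO_PA = 133.322

#: Linkage joints at which strength percent capable is evaluated, and the
#: strength-table joint name plus the muscle group demanded by a positive
#: (mass-anterior) / negative sagittal moment.
STRENGTH_JOINTS: dict[str, tuple[str, str, str]] = {
    "elbow": ("elbow", "flexion", "extension"),
    "shoulder": ("shoulder", "flexion", "extension"),
    "l5s1": ("torso", "extension", "flexion"),
    "hip": ("hip", "extension", "flexion"),
    "knee": ("knee", "extension", "flexion"),
    "ankle": ("ankle", "plantarflexion", "dorsiflexion"),
}


@dataclass
class L5S1Config:
    """Constants of the L5/S1 load model (SI units unless noted)."""

    erector_moment_arm_m: float = 0.05
    abdominal_moment_arm_m: float = 0.11
    diaphragm_area_m2: float = 0.0465
    pressure_coeff: float = 1e-4          # mmHg per (N*m)^exponent
    pressure_angle_const: float = 43.0
    pressure_angle_coeff: float = 0.36    # per degree
    pressure_moment_exponent: float = 1.8

    def __post_init__(self):
        if self.erector_moment_arm_m <= 0 or self.abdominal_moment_arm_m <= 0:
            raise ConfigurationError("moment arms must be positive")
        if self.diaphragm_area_m2 <= 0:
            raise ConfigurationError("diaphragm area must be positive")


@dataclass
class StrengthTable:
    """Population static strength moments (N*m) per joint and direction."""

    table: pd.DataFrame  # columns: joint, direction, mean_nm, sd_nm, population

    def __post_init__(self):
        if (self.table["mean_nm"] <= 0).any() or (self.table["sd_nm"] <= 0).any():
            raise ConfigurationError("strength means and SDs must be positive")
        self._index = self.table.set_index(["joint", "direction"])

    def mean_sd(self, joint: str, direction: str) -> tuple[float, float]:
        try:
            row = self._index.loc[(joint, direction)]
        except KeyError:
            raise CoverageError(
                f"strength table does not cover joint {joint!r} "
                f"direction {direction!r}"
            ) from None
        return float(row["mean_nm"]), float(row["sd_nm"])


def load_strength_table(path=None) -> StrengthTable:
    """The shipped literature-based default, or a user CSV with the same schema."""
    if path is None:
        with resources.files("ergopose.data").joinpath("strength_table.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return StrengthTable(df)


# ---------------------------------------------------------------------------
# segment-wise statics


def _chain_masses(
    coords: dict[str, np.ndarray], anthro: Anthropometry, load_kg: float
) -> list[tuple[str, str, list[tuple[float, np.ndarray]]]]:
    """The statics chain, distal to proximal.

    Each entry is (distal joint, proximal joint, [(mass_kg, com_xy), ...])
    listing the point masses whose weight first enters the balance at that
    link (bilateral limb segments count both sides).
    """
    c = {j: np.asarray(coords[j], dtype=float) for j in coords}
    missing = [j for j in LINKAGE_JOINTS if j not in c]
    if missing:
        raise ModelIncompleteError(f"linkage joints missing: {missing}")

    def com(proximal, distal, segment):
        return c[proximal] + anthro.com_fraction(segment) * (c[distal] - c[proximal])

    trunk_vec = c["shoulder"] - c["l5s1"]
    trunk_len = np.linalg.norm(trunk_vec)
    if trunk_len < 1e-9:
        raise ModelIncompleteError("shoulder and L5/S1 coincide")
    head_com = c["shoulder"] + (
        anthro.com_fraction("head_neck") * anthro.length("head_neck")
    ) * (trunk_vec / trunk_len)

    return [
        (
            "hand", "wrist",
            [
                (anthro.mass("hand", both_sides=True), com("wrist", "hand", "hand")),
                (load_kg, c["hand"]),
            ],
        ),
        ("wrist", "elbow",
         [(anthro.mass("forearm", both_sides=True), com("elbow", "wrist", "forearm"))]),
        ("elbow", "shoulder",
         [(anthro.mass("upper_arm", both_sides=True), com("shoulder", "elbow", "upper_arm"))]),
        (
            "shoulder", "l5s1",
            [
                (anthro.mass("trunk_upper"), com("l5s1", "shoulder", "trunk_upper")),
                (anthro.mass("head_neck"), head_com),
            ],
        ),
        ("l5s1", "hip",
         [(anthro.mass("pelvis"), com("hip", "l5s1", "pelvis"))]),
        ("hip", "knee",
         [(anthro.mass("thigh", both_sides=True), com("hip", "knee", "thigh"))]),
        ("knee", "ankle",
         [(anthro.mass("shank", both_sides=True), com("knee", "ankle", "shank"))]),
    ]


@dataclass
class StaticsFrameResult:
    """Per-frame output of the linkage statics and the L5/S1 analysis."""

    moments_nm: dict[str, float]          # signed sagittal moment per joint
    reactions_n: dict[str, np.ndarray]    # 2D reaction force per joint
    equilibrium_residuals: dict[str, float]
    pa_mmhg: float = 0.0
    fa_n: float = 0.0
    fm_n: float = 0.0
    fc_n: float = 0.0
    fs_n: float = 0.0
    percent_capable: dict[str, float] = field(default_factory=dict)

    @property
    def pa_pa(self) -> float:
        """Abdominal pressure in pascals."""
        return self.pa_mmhg * MMHG_TO_PA


def linkage_statics(
    coords: dict[str, np.ndarray], anthro: Anthropometry, load_kg: float = 0.0
) -> StaticsFrameResult:
    """Joint reaction forces and net moments for one planar posture.

    ``coords`` maps each linkage joint name to its sagittal (horizontal,
    vertical) coordinates in metres.  Distal-to-proximal recursion over the
    chain; positive moment = distal weight lies anterior (larger horizontal
    coordinate) to the joint.  The equilibrium residual stored per joint is
    the moment imbalance when the chain solution is re-checked against a
    direct free-body summation about that joint.
    """
    chain = _chain_masses(coords, anthro, load_kg)
    c = {j: np.asarray(coords[j], dtype=float) for j in coords}

    moments: dict[str, float] = {}
    reactions: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}

    supported = 0.0  # weight (N) supported at the current joint
    moment = 0.0
    all_masses: list[tuple[float, np.ndarray]] = []
    for distal, proximal, masses in chain:
        p = c[proximal]
        moment = moment + (c[distal][0] - p[0]) * supported
        for m, com in masses:
            moment += m * G * (com[0] - p[0])
            supported += m * G
            all_masses.append((m, com))
        moments[proximal] = moment
        reactions[proximal] = np.array([0.0, supported])
        # independent re-check: direct summation about this joint
        direct = sum(m * G * (com[0] - p[0]) for m, com in all_masses)
        force_closure = abs(supported - sum(m for m, _ in all_masses) * G)
        residuals[proximal] = max(abs(moment - direct), force_closure)
    return StaticsFrameResult(
        moments_nm=moments, reactions_n=reactions, equilibrium_residuals=residuals
    )


def l5s1_analysis(
    m_l5s1_nm: float,
    trunk_inclination_deg: float,
    thigh_inclination_deg: float,
    superincumbent_weight_n: float,
    config: L5S1Config | None = None,
) -> dict[str, float]:
    """Abdominal pressure/force, erector-spinae force, disc compression and
    shear from the L5/S1 moment.

    ``trunk_inclination_deg`` / ``thigh_inclination_deg`` are measured from
    the horizontal (90 = vertical).  The disc normal is taken along the
    trunk axis, so the superincumbent weight contributes
    ``W * sin(trunk inclination)`` to compression and ``W * cos`` to shear.
    """
    cfg = config or L5S1Config()
    theta_t = abs(float(trunk_inclination_deg))
    theta_h = abs(float(thigh_inclination_deg))
    m = abs(float(m_l5s1_nm))

    factor = cfg.pressure_angle_const - cfg.pressure_angle_coeff * (theta_h + theta_t)
    pa_mmhg = cfg.pressure_coeff * max(0.0, factor) * m ** cfg.pressure_moment_exponent
    fa = pa_mmhg * MMHG_TO_PA * cfg.diaphragm_area_m2
    fm = max(0.0, (m - fa * cfg.abdominal_moment_arm_m) / cfg.erector_moment_arm_m)
    w = float(superincumbent_weight_n)
    incl = math.radians(theta_t)
    fc = w * math.sin(incl) + fm - fa
    fs = w * math.cos(incl)
    return {"pa_mmhg": pa_mmhg, "fa_n": fa, "fm_n": fm, "fc_n": fc, "fs_n": fs}


def percent_capable(
    moments_nm: dict[str, float], strength: StrengthTable | None = None
) -> dict[str, float]:
    """Share of the population (%) strong enough for each joint's demand.

    Keys of ``moments_nm`` are linkage joint names; the moment sign selects
    the demanded muscle group (e.g. a mass-anterior moment at the torso
    demands the extensors).  Joints not covered by
    :data:`STRENGTH_JOINTS` raise :class:`~ergopose.errors.CoverageError`.
    """
    table = strength or load_strength_table()
    out = {}
    for joint, m in moments_nm.items():
        if joint not in STRENGTH_JOINTS:
            raise CoverageError(f"no strength mapping for joint {joint!r}")
        name, pos_dir, neg_dir = STRENGTH_JOINTS[joint]
        direction = pos_dir if m >= 0 else neg_dir
        mean, sd = table.mean_sd(name, direction)
        out[joint] = float(norm.cdf((mean - abs(m)) / sd) * 100.0)
    return out


# ---------------------------------------------------------------------------
# series-level analysis


@dataclass
class BiomechResultSeries:
    """Per-frame biomechanical results plus the projected linkage state."""

    frame_rate: float
    frames: pd.DataFrame
    linkage: LinkageStateSeries

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def summary(self) -> dict:
        fc = self.frames["fc_n"]
        return {
            "fc_min_n": float(fc.min()),
            "fc_mean_n": float(fc.mean()),
            "fc_max_n": float(fc.max()),
            "fc_max_frame": int(fc.idxmax()),
            "duration_s": len(self.frames) / self.frame_rate,
        }


def analyze_frame(
    linkage: LinkageStateSeries,
    i: int,
    anthro: Anthropometry,
    context: TaskContext,
    config: L5S1Config | None = None,
    strength: StrengthTable | None = None,
) -> StaticsFrameResult:
    """Full statics + L5/S1 + strength analysis of one linkage frame."""
    coords = linkage.frame_coords(i)
    res = linkage_statics(coords, anthro, context.load_kg)
    disc = l5s1_analysis(
        res.moments_nm["l5s1"],
        linkage.inclinations_deg["trunk"][i],
        # thigh inclination measured knee->hip; direction sign is irrelevant
        linkage.inclinations_deg["thigh"][i],
        float(res.reactions_n["l5s1"][1]),
        config,
    )
    res.pa_mmhg, res.fa_n, res.fm_n, res.fc_n, res.fs_n = (
        disc["pa_mmhg"], disc["fa_n"], disc["fm_n"], disc["fc_n"], disc["fs_n"],
    )
    res.percent_capable = percent_capable(
        {j: res.moments_nm[j] for j in STRENGTH_JOINTS}, strength
    )
    return res


def analyze_series(
    positions: SegmentPositionSeries,
    anthro: Anthropometry,
    context: TaskContext,
    plane_definition: str = "pelvis-heading",
    config: L5S1Config | None = None,
    strength: StrengthTable | None = None,
) -> BiomechResultSeries:
    """Project a position series to the sagittal plane and analyse each frame."""
    if positions.n_frames == 0:
        raise EmptyInputError("empty position series")
    strength = strength or load_strength_table()
    linkage = project_sagittal(positions, plane_definition)
    rows = []
    for i in range(linkage.n_frames):
        try:
            r = analyze_frame(linkage, i, anthro, context, config, strength)
        except Exception as exc:
            raise FrameError(i, exc) from exc
        row = {"frame": i, "time": float(linkage.timestamps[i])}
        for j, m in r.moments_nm.items():
            row[f"moment_{j}_nm"] = m
        for j, f in r.reactions_n.items():
            row[f"reaction_{j}_n"] = float(f[1])
        row.update(
            pa_mmhg=r.pa_mmhg, fa_n=r.fa_n, fm_n=r.fm_n, fc_n=r.fc_n, fs_n=r.fs_n
        )
        for j, pc in r.percent_capable.items():
            row[f"pc_{j}_pct"] = pc
        row["equilibrium_residual_max"] = max(r.equilibrium_residuals.values())
        rows.append(row)
    return BiomechResultSeries(
        frame_rate=positions.frame_rate, frames=pd.DataFrame(rows), linkage=linkage
    )
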