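"""Independent oracles for the test suite.

Everything here is deliberately written as a *separate transcription /
separate algorithm* from the package under test: the RULA/REBA tables are
re-entered row by row in a different encoding, region thresholds are
re-stated as plain if/else chains, the statics oracle sums every free body
directly instead of recursing, and the ICC oracle computes the two-way
ANOVA table by hand.  The oracles never import scoring or statics code from
``ergopose``.
"""

from __future__ import annotations

import math

import numpy as np

G = 9.80665

# ---------------------------------------------------------------------------
# RULA tables, re-entered as digit strings (order: wrist 1-4 x twist 1-2)

_RULA_A_ROWS = {
    (1, 1): "12222333", (1, 2): "22223333", (1, 3): "23333344",
    (2, 1): "23333444", (2, 2): "33333444", (2, 3): "34444455",
    (3, 1): "33444455", (3, 2): "34444455", (3, 3): "44444555",
    (4, 1): "44444555", (4, 2): "44444555", (4, 3): "44455566",
    (5, 1): "55555667", (5, 2): "56666777", (5, 3): "66677778",
    (6, 1): "77777889", (6, 2): "88888999", (6, 3): "99999999",
}

# order: trunk 1-6 x legs 1-2
_RULA_B_ROWS = {
    1: "132334556677",
    2: "232345556777",
    3: "333445566777",
    4: "555667777788",
    5: "777778888888",
    6: "888888899999",
}

_RULA_C_ROWS = {
    1: "1233455", 2: "2234455", 3: "3334456", 4: "3334566",
    5: "4445677", 6: "4456677", 7: "5566777", 8: "5567777",
}


def rula_table_a(ua: int, la: int, wrist: int, twist: int) -> int:
    return int(_RULA_A_ROWS[(ua, la)][(wrist - 1) * 2 + (twist - 1)])


def rula_table_b(neck: int, trunk: int, legs: int) -> int:
    return int(_RULA_B_ROWS[neck][(trunk - 1) * 2 + (legs - 1)])


def rula_table_c(c: int, d: int) -> int:
    return int(_RULA_C_ROWS[min(c, 8)][min(d, 7) - 1])


def rula_grand(
    ua: int, la: int, wrist: int, twist: int, neck: int, trunk: int, legs: int,
    muscle: int, force: int,
) -> int:
    a = rula_table_a(ua, la, wrist, twist)
    b = rula_table_b(neck, trunk, legs)
    return rula_table_c(a + muscle + force, b + muscle + force)


def rula_risk(grand: int) -> str:
    if grand <= 2:
        return "negligible"
    if grand <= 4:
        return "low"
    if grand <= 6:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# REBA tables (A: neck x trunk -> legs digits; B: lower arm x upper arm ->
# wrist digits; C: full integer rows)

_REBA_A = {
    1: ["1234", "2345", "2456", "3567", "4678"],
    2: ["1234", "3456", "4567", "5678", "6789"],
    3: ["3356", "4567", "5678", "6789", "7899"],
}

_REBA_B = {
    1: ["122", "123", "345", "455", "678", "788"],
    2: ["123", "234", "455", "567", "788", "899"],
}

_REBA_C = [
    [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7],
    [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8],
    [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8],
    [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9],
    [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9],
    [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10],
    [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11],
    [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11],
    [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12],
    [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12],
    [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12],
    [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12],
]


def reba_table_a(neck: int, trunk: int, legs: int) -> int:
    return int(_REBA_A[neck][trunk - 1][legs - 1])


def reba_table_b(la: int, ua: int, wrist: int) -> int:
    return int(_REBA_B[la][ua - 1][wrist - 1])


def reba_table_c(a: int, b: int) -> int:
    return _REBA_C[min(a, 12) - 1][min(b, 12) - 1]


def reba_grand(
    trunk: int, neck: int, legs: int, ua: int, la: int, wrist: int,
    load_score: int, coupling_score: int, activity: int,
) -> int:
    a = reba_table_a(neck, trunk, legs) + load_score
    b = reba_table_b(la, ua, wrist) + coupling_score
    return reba_table_c(a, b) + activity


def reba_risk(grand: int) -> str:
    if grand == 1:
        return "negligible"
    if grand <= 3:
        return "low"
    if grand <= 7:
        return "medium"
    if grand <= 10:
        return "high"
    return "very_high"


# ---------------------------------------------------------------------------
# worksheet region thresholds, re-stated as if/else chains over a posture
# description (the same named angles a PostureSpec carries)


def rula_regions_from_posture(p: dict) -> dict[str, int]:
    t = p.get

    ua_f = t("shoulder_flexion", 0.0)
    if ua_f < -20 or 20 <= ua_f < 45:
        ua = 2
    elif -20 <= ua_f < 20:
        ua = 1
    elif 45 <= ua_f < 90:
        ua = 3
    else:
        ua = 4
    if abs(t("shoulder_elevation", 0.0)) > 15:
        ua += 1
    if abs(t("shoulder_abduction", 0.0)) > 45:
        ua += 1
    if t("arm_supported", False):
        ua = max(1, ua - 1)

    la = 1 if 60 <= t("elbow_flexion", 0.0) < 100 else 2
    if abs(t("shoulder_rotation", 0.0)) > 60:
        la += 1

    w_f = t("wrist_flexion", 0.0)
    if abs(w_f) < 5:
        w = 1
    elif abs(w_f) < 15:
        w = 2
    else:
        w = 3
    if abs(t("wrist_deviation", 0.0)) > 15:
        w += 1
    wt = 2 if abs(t("wrist_rotation", 0.0)) > 60 else 1

    n_f = t("neck_flexion", 0.0)
    if n_f < -5:
        neck = 4
    elif n_f < 10:
        neck = 1
    elif n_f < 20:
        neck = 2
    else:
        neck = 3
    if abs(t("neck_twist", 0.0)) > 20:
        neck += 1
    if abs(t("neck_side_bend", 0.0)) > 20:
        neck += 1

    t_f = t("trunk_flexion", 0.0)
    if abs(t_f) <= 5 and t_f > -5:
        trunk = 1
    elif t_f < -5 or t_f < 20:
        trunk = 2
    elif t_f < 60:
        trunk = 3
    else:
        trunk = 4
    if abs(t("trunk_twist", 0.0)) > 20:
        trunk += 1
    if abs(t("trunk_side_bend", 0.0)) > 20:
        trunk += 1

    legs = 1 if t("legs_supported", True) else 2
    return {"upper_arm": ua, "lower_arm": la, "wrist": w, "wrist_twist": wt,
            "neck": neck, "trunk": trunk, "legs": legs}


def rula_force_score(load_kg: float, sustained: bool, shock: bool) -> int:
    if shock:
        return 3
    if load_kg < 2:
        return 0
    if load_kg < 10:
        return 2 if sustained else 1
    return 3


def rula_label(p: dict) -> tuple[int, str]:
    r = rula_regions_from_posture(p)
    muscle = 1 if p.get("muscle_use_static", False) else 0
    force = rula_force_score(
        p.get("load_kg", 0.0), p.get("muscle_use_static", False),
        p.get("shock_or_rapid_buildup", False),
    )
    grand = rula_grand(
        r["upper_arm"], r["lower_arm"], r["wrist"], r["wrist_twist"],
        r["neck"], r["trunk"], r["legs"], muscle, force,
    )
    return grand, rula_risk(grand)


def reba_regions_from_posture(p: dict) -> dict[str, int]:
    t = p.get

    t_f = t("trunk_flexion", 0.0)
    if -5 < t_f <= 5:
        trunk = 1
    elif -20 < t_f <= -5 or 5 < t_f < 20:
        trunk = 2
    elif t_f <= -20 or 20 <= t_f < 60:
        trunk = 3
    else:
        trunk = 4
    if abs(t("trunk_twist", 0.0)) > 20 or abs(t("trunk_side_bend", 0.0)) > 20:
        trunk += 1

    n_f = t("neck_flexion", 0.0)
    neck = 1 if -5 <= n_f < 20 else 2
    if abs(t("neck_twist", 0.0)) > 20 or abs(t("neck_side_bend", 0.0)) > 20:
        neck += 1

    legs = 1 if t("legs_supported", True) else 2
    knee = abs(t("knee_flexion", 0.0))
    if 30 <= knee < 60:
        legs += 1
    elif knee >= 60:
        legs += 2

    ua_f = t("shoulder_flexion", 0.0)
    if -20 <= ua_f < 20:
        ua = 1
    elif ua_f < -20 or ua_f < 45:
        ua = 2
    elif ua_f < 90:
        ua = 3
    else:
        ua = 4
    if abs(t("shoulder_abduction", 0.0)) > 45 or abs(t("shoulder_rotation", 0.0)) > 60:
        ua += 1
    if abs(t("shoulder_elevation", 0.0)) > 15:
        ua += 1
    if t("arm_supported", False):
        ua = max(1, ua - 1)

    la = 1 if 60 <= t("elbow_flexion", 0.0) < 100 else 2

    w_f = t("wrist_flexion", 0.0)
    w = 1 if abs(w_f) < 15 else 2
    if abs(t("wrist_deviation", 0.0)) > 15 or abs(t("wrist_rotation", 0.0)) > 60:
        w += 1

    return {"trunk": trunk, "neck": neck, "legs": legs,
            "upper_arm": ua, "lower_arm": la, "wrist": w}


def reba_load_score(load_kg: float, shock: bool) -> int:
    if load_kg < 5:
        s = 0
    elif load_kg <= 10:
        s = 1
    else:
        s = 2
    return s + (1 if shock else 0)


_COUPLING = {"good": 0, "fair": 1, "poor": 2, "unacceptable": 3}


def reba_label(p: dict) -> tuple[int, str]:
    r = reba_regions_from_posture(p)
    load = reba_load_score(
        p.get("load_kg", 0.0), p.get("shock_or_rapid_buildup", False)
    )
    coupling = _COUPLING[p.get("coupling", "good")]
    activity = sum(
        bool(p.get(k, False))
        for k in ("activity_static_hold", "activity_repeated", "activity_rapid_change")
    )
    grand = reba_grand(
        r["trunk"], r["neck"], r["legs"], r["upper_arm"], r["lower_arm"],
        r["wrist"], load, coupling, activity,
    )
    return grand, reba_risk(grand)


# ---------------------------------------------------------------------------
# brute-force planar statics: direct free-body summation per joint


def statics_oracle(
    coords: dict[str, np.ndarray],
    seg_table,  # anthropometry DataFrame indexed by segment
    body_mass_kg: float,
    stature_m: float,
    load_kg: float,
) -> dict[str, dict]:
    """Moments and reactions at every linkage joint by summing, for each
    joint, weight x lever over every point mass distal to it."""
    c = {k: np.asarray(v, dtype=float) for k, v in coords.items()}

    def seg_mass(name):
        row = seg_table.loc[name]
        return row["mass_fraction"] * body_mass_kg * (2.0 if row["bilateral"] else 1.0)

    def com(a, b, name):
        return c[a] + seg_table.loc[name, "com_fraction_from_proximal"] * (c[b] - c[a])

    trunk_dir = c["shoulder"] - c["l5s1"]
    trunk_dir = trunk_dir / np.linalg.norm(trunk_dir)
    head_com = c["shoulder"] + (
        seg_table.loc["head_neck", "com_fraction_from_proximal"]
        * seg_table.loc["head_neck", "length_fraction"] * stature_m
    ) * trunk_dir

    masses = [
        (load_kg, c["hand"]),
        (seg_mass("hand"), com("wrist", "hand", "hand")),
        (seg_mass("forearm"), com("elbow", "wrist", "forearm")),
        (seg_mass("upper_arm"), com("shoulder", "elbow", "upper_arm")),
        (seg_mass("trunk_upper"), com("l5s1", "shoulder", "trunk_upper")),
        (seg_mass("head_neck"), head_com),
        (seg_mass("pelvis"), com("hip", "l5s1", "pelvis")),
        (seg_mass("thigh"), com("hip", "knee", "thigh")),
        (seg_mass("shank"), com("knee", "ankle", "shank")),
    ]
    # masses supported at each joint: cumulative prefix of the list above
    cutoffs = {
        "wrist": 2, "elbow": 3, "shoulder": 4, "l5s1": 6, "hip": 7,
        "knee": 8, "ankle": 9,
    }
    out = {}
    for joint, k in cutoffs.items():
        sub = masses[:k]
        weight = sum(m for m, _ in sub) * G
        moment = sum(m * G * (p[0] - c[joint][0]) for m, p in sub)
        out[joint] = {"moment": moment, "weight": weight}
    return out


def l5s1_oracle(
    m_nm: float, trunk_incl_deg: float, thigh_incl_deg: float, w_n: float,
    E=0.05, D=0.11, area=0.0465,
) -> dict[str, float]:
    """Spreadsheet-style re-computation of the disc load chain."""
    m = abs(m_nm)
    factor = 43.0 - 0.36 * (abs(thigh_incl_deg) + abs(trunk_incl_deg))
    pa = 1e-4 * max(0.0, factor) * m ** 1.8
    fa = pa * 133.322 * area
    fm = max(0.0, (m - fa * D) / E)
    fc = w_n * math.sin(math.radians(abs(trunk_incl_deg))) + fm - fa
    fs = w_n * math.cos(math.radians(abs(trunk_incl_deg)))
    return {"pa_mmhg": pa, "fa_n": fa, "fm_n": fm, "fc_n": fc, "fs_n": fs}


# ---------------------------------------------------------------------------
# statistics oracles


def icc21_oracle(m: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA table, written out long-hand."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def cmc_oracle(y: np.ndarray) -> float:
    """Direct transcription of the intersystem CMC formula."""
    y = np.asarray(y, dtype=float)
    f, s = y.shape
    gbar = y.mean()
    fbar = y.mean(axis=1)
    num = sum((y[i, j] - fbar[i]) ** 2 for i in range(f) for j in range(s))
    den = sum((y[i, j] - gbar) ** 2 for i in range(f) for j in range(s))
    num /= f * (s - 1)
    den /= f * s - 1
    return math.sqrt(max(0.0, 1 - num / den))
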