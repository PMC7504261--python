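"""RULA scoring: threshold bins, table chain, series operations."""

import itertools

import numpy as np
import pytest

import oracles
from ergopose import rula
from ergopose.context import TaskContext
from ergopose.errors import EmptyInputError, FrameError, TableLookupError
from ergopose.scoring import PostureFrame, SidePosture, find_max, summarize
from ergopose.series import JointAngleSeries
from ergopose.synthmotion import generate_posture_series, get_posture


def make_posture(**kwargs) -> PostureFrame:
    side_fields = dict(
        upper_arm_flexion=0.0, shoulder_abduction=0.0, shoulder_rotation=0.0,
        shoulder_elevation=0.0, elbow_flexion=0.0, wrist_flexion=0.0,
        wrist_deviation=0.0, wrist_rotation=0.0, knee_flexion=0.0,
    )
    frame_fields = dict(
        trunk_flexion=0.0, trunk_twist=0.0, trunk_side_bend=0.0,
        neck_flexion=0.0, neck_twist=0.0, neck_side_bend=0.0,
    )
    for k, v in kwargs.items():
        (side_fields if k in side_fields else frame_fields)[k] = v
    side = SidePosture(**side_fields)
    return PostureFrame(**frame_fields, right=side, left=SidePosture(**side_fields))


@pytest.mark.parametrize(
    "kwargs, region, expected",
    [
        ({}, "upper_arm", 1),
        ({}, "trunk", 1),
        ({}, "neck", 1),
        ({}, "lower_arm", 2),            # a hanging straight arm scores 2
        ({"upper_arm_flexion": 95.0}, "upper_arm", 4),
        ({"upper_arm_flexion": 95.0, "shoulder_abduction": 60.0}, "upper_arm", 5),
        ({"upper_arm_flexion": 30.0}, "upper_arm", 2),
        ({"upper_arm_flexion": -30.0}, "upper_arm", 2),
        ({"elbow_flexion": 80.0}, "lower_arm", 1),
        ({"elbow_flexion": 120.0}, "lower_arm", 2),
        ({"wrist_flexion": 10.0}, "wrist", 2),
        ({"wrist_flexion": 20.0, "wrist_deviation": 20.0}, "wrist", 4),
        ({"wrist_rotation": 70.0}, "wrist_twist", 2),
        ({"neck_flexion": 15.0}, "neck", 2),
        ({"neck_flexion": -10.0}, "neck", 4),
        ({"trunk_flexion": 30.0}, "trunk", 3),
        ({"trunk_flexion": 70.0, "trunk_twist": 30.0}, "trunk", 5),
    ],
)
def test_region_threshold_bins(kwargs, region, expected):
    regions = rula.rula_region_scores(make_posture(**kwargs), TaskContext())
    assert regions[region] == expected


def test_arm_support_lowers_upper_arm_score_with_floor():
    ctx = TaskContext(arm_supported=True)
    assert rula.rula_region_scores(make_posture(), ctx)["upper_arm"] == 1
    raised = make_posture(upper_arm_flexion=95.0)
    assert rula.rula_region_scores(raised, ctx)["upper_arm"] == 3


def test_neutral_posture_grand_is_two():
    res = rula.score_frame(make_posture(), TaskContext())
    assert res.grand == 2
    assert res.risk_level == "negligible"


def test_out_of_domain_region_score_raises_not_clamps():
    regions = rula.rula_region_scores(make_posture(), TaskContext())
    regions["upper_arm"] = 7
    with pytest.raises(TableLookupError):
        rula.rula_grand(regions, TaskContext())


def test_grand_matches_brute_force_oracle_exhaustively():
    """Every valid region-score tuple x muscle x force: zero mismatches."""
    ctx_plain = TaskContext()
    tables = rula.load_tables("rula")
    for ua, la, w, wt in itertools.product(
        range(1, 7), range(1, 4), range(1, 5), range(1, 3)
    ):
        for n, t, l in itertools.product(range(1, 7), range(1, 7), range(1, 3)):
            regions = {
                "upper_arm": ua, "lower_arm": la, "wrist": w, "wrist_twist": wt,
                "neck": n, "trunk": t, "legs": l,
            }
            res = rula.rula_grand(regions, ctx_plain, tables=tables)
            assert res.grand == oracles.rula_grand(ua, la, w, wt, n, t, l, 0, 0)
            assert res.risk_level == oracles.rula_risk(res.grand)


def test_grand_monotone_in_force_and_muscle_scores():
    tables = rula.load_tables("rula")
    contexts = [
        TaskContext(),                                            # force 0
        TaskContext(load_kg=5.0),                                 # force 1
        TaskContext(load_kg=5.0, muscle_use_static=True),         # force 2 + muscle
        TaskContext(load_kg=12.0, muscle_use_static=True),        # force 3 + muscle
    ]
    for ua, n in itertools.product(range(1, 7), range(1, 7)):
        regions = {
            "upper_arm": ua, "lower_arm": 1, "wrist": 1, "wrist_twist": 1,
            "neck": n, "trunk": 1, "legs": 1,
        }
        grands = [
            rula.rula_grand(regions, c, tables=tables).grand for c in contexts
        ]
        assert grands == sorted(grands)


def test_worse_side_is_reported():
    side = dict(
        upper_arm_flexion=0.0, shoulder_abduction=0.0, shoulder_rotation=0.0,
        shoulder_elevation=0.0, elbow_flexion=80.0, wrist_flexion=0.0,
        wrist_deviation=0.0, wrist_rotation=0.0, knee_flexion=0.0,
    )
    left = dict(side, upper_arm_flexion=110.0)
    posture = PostureFrame(
        trunk_flexion=0, trunk_twist=0, trunk_side_bend=0,
        neck_flexion=0, neck_twist=0, neck_side_bend=0,
        right=SidePosture(**side), left=SidePosture(**left),
    )
    res = rula.score_frame(posture, TaskContext())
    assert res.side == "left"
    assert res.upper_arm == 4


def test_score_series_constant_posture_and_summary():
    spec = get_posture("neutral_standing", duration_s=5.0)
    angles, _, _ = generate_posture_series(spec)
    scores = rula.score_series(angles, spec.context())
    assert scores.n_frames == 100
    assert set(scores.grand) == {2}
    s = summarize(scores)
    assert s["average_grand"] == 2.0
    assert s["duration_s"] == pytest.approx(5.0)
    assert s["grand_distribution"] == {2: 1.0}
    assert sum(s["risk_distribution"].values()) == pytest.approx(1.0)


def test_summary_arithmetic_on_known_scores():
    import pandas as pd

    from ergopose.scoring import ErgoScoreSeries

    frames = pd.DataFrame(
        {"grand": [3, 3, 5], "risk_level": ["low", "low", "medium"]}
    )
    scores = ErgoScoreSeries(method="RULA", frame_rate=1.0, frames=frames)
    s = summarize(scores)
    assert s["average_grand"] == pytest.approx(11 / 3)
    assert s["duration_s"] == pytest.approx(3.0)
    assert s["grand_distribution"] == {3: pytest.approx(2 / 3), 5: pytest.approx(1 / 3)}


@pytest.mark.parametrize(
    "grands, expected",
    [([2, 5, 5, 3], 1), ([4, 4, 4], 0), ([1, 2, 3, 4], 3)],
)
def test_find_max_earliest_tie_break(grands, expected):
    import pandas as pd

    from ergopose.scoring import ErgoScoreSeries

    scores = ErgoScoreSeries(
        method="RULA", frame_rate=1.0,
        frames=pd.DataFrame({"grand": grands, "risk_level": ["low"] * len(grands)}),
    )
    assert find_max(scores) == expected


def test_alternating_postures_alternate_grand_scores():
    neutral = get_posture("neutral_standing")
    deep = get_posture("deep_stoop_lift_5kg")
    from ergopose.synthmotion import _angle_frame

    frames = np.stack(
        [_angle_frame((neutral if i % 2 == 0 else deep).angle_values())
         for i in range(10)]
    )
    series = JointAngleSeries(
        frame_rate=10.0, timestamps=np.arange(10) / 10.0, angles=frames
    )
    scores = rula.score_series(series, deep.context())
    # context (5 kg) is shared, so the neutral frames score the loaded value
    assert list(np.unique(scores.grand[::2])) == [3]
    assert list(np.unique(scores.grand[1::2])) == [7]


def test_empty_series_is_rejected():
    with pytest.raises(EmptyInputError):
        JointAngleSeries(frame_rate=20.0, timestamps=np.array([]), angles=np.zeros((0, 22, 3)))


def test_nonphysiological_angle_raises_with_frame_index():
    spec = get_posture("neutral_standing")
    angles, _, _ = generate_posture_series(spec)
    arr = angles.angles.copy()
    arr[5, 0, 0] = 200.0  # trunk joint flexion beyond 180
    bad = JointAngleSeries(
        frame_rate=angles.frame_rate, timestamps=angles.timestamps, angles=arr
    )
    with pytest.raises(FrameError) as err:
        rula.score_series(bad, TaskContext())
    assert err.value.frame == 5
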