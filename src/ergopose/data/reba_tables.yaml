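# REBA scoring tables and thresholds, transcribed from the original REBA
# publication (Hignett & McAtamney, 2000).  version 1.
#
# Schema mirrors rula_tables.yaml:
#   bins: [lower, upper, score] with lower <= angle < upper; +/-5 deg
#     neutral tolerances are this package's declared robustness thresholds.
#   table_a: [neck 1-3][trunk 1-5][legs 1-4]
#   table_b: [lower_arm 1-2][upper_arm 1-6][wrist 1-3]
#   table_c: [score_A 1-12][score_B 1-12]
version: "1"
method: REBA

bins:
  trunk:                           # trunk flexion; extension negative
    - [-.inf, -20.0, 3]
    - [-20.0, -5.0, 2]
    - [-5.0, 5.0, 1]
    - [5.0, 20.0, 2]
    - [20.0, 60.0, 3]
    - [60.0, .inf, 4]
  neck:                            # neck flexion; extension scores 2
    - [-.inf, -5.0, 2]
    - [-5.0, 20.0, 1]
    - [20.0, .inf, 2]
  upper_arm:
    - [-.inf, -20.0, 2]
    - [-20.0, 20.0, 1]
    - [20.0, 45.0, 2]
    - [45.0, 90.0, 3]
    - [90.0, .inf, 4]
  lower_arm:
    - [-.inf, 60.0, 2]
    - [60.0, 100.0, 1]
    - [100.0, .inf, 2]
  wrist:
    - [-.inf, -15.0, 2]
    - [-15.0, 15.0, 1]
    - [15.0, .inf, 2]
  knee_increment:                  # added to the legs base score
    - [-.inf, 30.0, 0]
    - [30.0, 60.0, 1]
    - [60.0, .inf, 2]

cues:
  shoulder_abduction_deg: 45.0     # upper arm abducted (+1, shared with "rotated")
  arm_rotation_deg: 60.0           # upper arm rotated (+1, shared with "abducted")
  shoulder_raised_deg: 15.0        # shoulder girdle elevated (+1)
  wrist_deviation_deg: 15.0        # wrist deviated or twisted (+1, shared)
  wrist_twist_deg: 60.0
  twist_deg: 20.0                  # trunk/neck twisted (+1, shared with side-bend)
  side_bend_deg: 20.0

load_bands:                        # added to table-A score
  - {min_kg: 0.0, max_kg: 5.0, score: 0}
  - {min_kg: 5.0, max_kg: 10.0, score: 1}
  - {min_kg: 10.0, max_kg: .inf, score: 2}
load_max_kg_inclusive: 10.0        # a 10 kg load still scores 1
shock_increment: 1                 # +1 for shock or rapid build-up

coupling_scores: {good: 0, fair: 1, poor: 2, unacceptable: 3}

table_a:                           # [neck][trunk][legs]
  - - [1, 2, 3, 4]
    - [2, 3, 4, 5]
    - [2, 4, 5, 6]
    - [3, 5, 6, 7]
    - [4, 6, 7, 8]
  - - [1, 2, 3, 4]
    - [3, 4, 5, 6]
    - [4, 5, 6, 7]
    - [5, 6, 7, 8]
    - [6, 7, 8, 9]
  - - [3, 3, 5, 6]
    - [4, 5, 6, 7]
    - [5, 6, 7, 8]
    - [6, 7, 8, 9]
    - [7, 8, 9, 9]

table_b:                           # [lower_arm][upper_arm][wrist]
  - - [1, 2, 2]
    - [1, 2, 3]
    - [3, 4, 5]
    - [4, 5, 5]
    - [6, 7, 8]
    - [7, 8, 8]
  - - [1, 2, 3]
    - [2, 3, 4]
    - [4, 5, 5]
    - [5, 6, 7]
    - [7, 8, 8]
    - [8, 9, 9]

table_c:                           # [score_A][score_B], both 1-12
  - [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7]
  - [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8]
  - [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8]
  - [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9]
  - [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9]
  - [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10]
  - [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11]
  - [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11]
  - [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12]
  - [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12]
  - [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12]
  - [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12]

risk_bands:
  negligible: [1, 1]
  low: [2, 3]
  medium: [4, 7]
  high: [8, 10]
  very_high: [11, 15]
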