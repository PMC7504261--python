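# RULA scoring tables and thresholds, transcribed from the original RULA
# worksheet (McAtamney & Corlett, 1993).  version 1.
#
# Schema:
#   bins: list of [lower, upper, score]; a flexion angle t (degrees,
#     extension negative) scores the row with lower <= t < upper.
#     Neutral tolerances of +/-5 deg around 0 keep "upright"/"straight"
#     judgements robust to sensor noise; they are this package's declared
#     thresholds, not part of the original worksheet.
#   table_a: [upper_arm 1-6][lower_arm 1-3][wrist 1-4][wrist_twist 1-2]
#   table_b: [neck 1-6][trunk 1-6][legs 1-2]
#   table_c: [score_C 1-8+][score_D 1-7+]  (8+/7+ rows/cols saturate)
#   cues: thresholds (degrees) for the boolean posture adjustments.
version: "1"
method: RULA

bins:
  upper_arm:                       # shoulder flexion/extension
    - [-.inf, -20.0, 2]
    - [-20.0, 20.0, 1]
    - [20.0, 45.0, 2]
    - [45.0, 90.0, 3]
    - [90.0, .inf, 4]
  lower_arm:                       # elbow flexion
    - [-.inf, 60.0, 2]
    - [60.0, 100.0, 1]
    - [100.0, .inf, 2]
  wrist:                           # wrist flexion/extension
    - [-.inf, -15.0, 3]
    - [-15.0, -5.0, 2]
    - [-5.0, 5.0, 1]
    - [5.0, 15.0, 2]
    - [15.0, .inf, 3]
  neck:                            # neck flexion; extension scores 4
    - [-.inf, -5.0, 4]
    - [-5.0, 10.0, 1]
    - [10.0, 20.0, 2]
    - [20.0, .inf, 3]
  trunk:                           # trunk flexion; extension treated as slight flexion
    - [-.inf, -5.0, 2]
    - [-5.0, 5.0, 1]
    - [5.0, 20.0, 2]
    - [20.0, 60.0, 3]
    - [60.0, .inf, 4]

cues:
  shoulder_abduction_deg: 45.0     # +1 upper arm if abducted beyond this
  shoulder_raised_deg: 15.0        # +1 upper arm if shoulder girdle elevated
  arm_midline_rotation_deg: 60.0   # +1 lower arm if working across midline / out to side
  wrist_deviation_deg: 15.0        # +1 wrist if ulnar/radial deviation
  wrist_twist_end_range_deg: 60.0  # wrist-twist score 2 at/near end of pronation range
  twist_deg: 20.0                  # +1 neck/trunk if twisted beyond this
  side_bend_deg: 20.0              # +1 neck/trunk if side-bent beyond this

# Force/load score; "sustained" means static hold or repeated action.
force_bands:
  - {min_kg: 0.0, max_kg: 2.0, intermittent: 0, sustained: 0}
  - {min_kg: 2.0, max_kg: 10.0, intermittent: 1, sustained: 2}
  - {min_kg: 10.0, max_kg: .inf, intermittent: 3, sustained: 3}
shock_score: 3                     # shock or rapid force build-up

table_a:                           # [upper_arm][lower_arm][wrist][wrist_twist]
  - - [[1, 2], [2, 2], [2, 3], [3, 3]]
    - [[2, 2], [2, 2], [3, 3], [3, 3]]
    - [[2, 3], [3, 3], [3, 3], [4, 4]]
  - - [[2, 3], [3, 3], [3, 4], [4, 4]]
    - [[3, 3], [3, 3], [3, 4], [4, 4]]
    - [[3, 4], [4, 4], [4, 4], [5, 5]]
  - - [[3, 3], [4, 4], [4, 4], [5, 5]]
    - [[3, 4], [4, 4], [4, 4], [5, 5]]
    - [[4, 4], [4, 4], [4, 5], [5, 5]]
  - - [[4, 4], [4, 4], [4, 5], [5, 5]]
    - [[4, 4], [4, 4], [4, 5], [5, 5]]
    - [[4, 4], [4, 5], [5, 5], [6, 6]]
  - - [[5, 5], [5, 5], [5, 6], [6, 7]]
    - [[5, 6], [6, 6], [6, 7], [7, 7]]
    - [[6, 6], [6, 7], [7, 7], [7, 8]]
  - - [[7, 7], [7, 7], [7, 8], [8, 9]]
    - [[8, 8], [8, 8], [8, 9], [9, 9]]
    - [[9, 9], [9, 9], [9, 9], [9, 9]]

table_b:                           # [neck][trunk][legs]
  - [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]]
  - [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]]
  - [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]]
  - [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]]
  - [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]]
  - [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]]

table_c:                           # [score_C][score_D]
  - [1, 2, 3, 3, 4, 5, 5]
  - [2, 2, 3, 4, 4, 5, 5]
  - [3, 3, 3, 4, 4, 5, 6]
  - [3, 3, 3, 4, 5, 6, 6]
  - [4, 4, 4, 5, 6, 7, 7]
  - [4, 4, 5, 6, 6, 7, 7]
  - [5, 5, 6, 6, 7, 7, 7]
  - [5, 5, 6, 7, 7, 7, 7]

# Grand-score -> risk-level bands.  The published band wording overlaps at
# grand = 6 ("medium 5-6, high 6+"); this package resolves 6 to medium and
# 7 to high so the map is a partition of 1-7.  Configurable.
risk_bands:
  negligible: [1, 2]
  low: [3, 4]
  medium: [5, 6]
  high: [7, 7]
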