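"""Manual task-context inputs.

These are the analyst-supplied settings that cannot be derived from the
motion itself: hand load, coupling quality, muscle-use and activity flags,
and the subject's mass and stature.  Defaults describe an unloaded standing
task by a subject of average build for a young male cohort
(68.4 kg, 1.731 m).
"""

from __future__ import annotations

from dataclasses import dataclass

COUPLING_LEVELS = ("good", "fair", "poor", "unacceptable")


@dataclass
class TaskContext:
    """Manual inputs for postural scoring and biomechanics.

    Parameters
    ----------
    load_kg : hand-held load mass, kg (>= 0).
    coupling : hand-object interface quality, one of good/fair/poor/unacceptable.
    muscle_use_static : posture held > 1 min or action repeated > 4x/min
        (drives the RULA muscle-use score and the static/repeated load band).
    shock_or_rapid_buildup : forces applied as shocks or built up rapidly.
    arm_supported : upper arm supported or person leaning (-1 upper-arm score).
    legs_supported : legs and feet supported and balanced.
    activity_static_hold / activity_repeated / activity_rapid_change :
        whole-body activity flags (+1 each on the REBA activity score).
    subject_mass_kg, subject_height_m : anthropometric scaling inputs.
    """

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

    def __post_init__(self):
        if self.load_kg < 0:
            raise ValueError("load_kg must be >= 0")
        if self.coupling not in COUPLING_LEVELS:
            raise ValueError(
                f"coupling must be one of {COUPLING_LEVELS}, got {self.coupling!r}"
            )
        if self.subject_mass_kg <= 0 or self.subject_height_m <= 0:
            raise ValueError("subject mass and height must be positive")
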