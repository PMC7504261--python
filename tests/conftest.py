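import numpy as np
import pytest

from ergopose.anthro import default_anthropometry
from ergopose.context import TaskContext
from ergopose.synthmotion import generate_posture_series, get_posture


@pytest.fixture(scope="session")
def anthro():
    return default_anthropometry(68.4, 1.731)


@pytest.fixture(scope="session")
def neutral_context():
    return TaskContext()


@pytest.fixture(scope="session")
def neutral_series():
    """Zero-noise neutral-standing angle+position series (2 s at 20 Hz)."""
    spec = get_posture("neutral_standing", duration_s=2.0)
    angles, positions, label = generate_posture_series(spec)
    return spec, angles, positions, label


def random_planar_posture(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """A random but anatomically ordered planar linkage posture (metres)."""
    ankle = np.array([0.0, 0.07])
    knee = ankle + _polar(rng, 0.42, 60, 120)
    hip = knee + _polar(rng, 0.42, 40, 120)
    l5s1 = hip + _polar(rng, 0.12, 10, 120)
    shoulder = l5s1 + _polar(rng, 0.38, 10, 120)
    elbow = shoulder + _polar(rng, 0.32, -120, 60)
    wrist = elbow + _polar(rng, 0.25, -120, 90)
    hand = wrist + _polar(rng, 0.08, -120, 90)
    return {
        "ankle": ankle, "knee": knee, "hip": hip, "l5s1": l5s1,
        "shoulder": shoulder, "elbow": elbow, "wrist": wrist, "hand": hand,
    }


def _polar(rng, length, lo_deg, hi_deg):
    a = np.radians(rng.uniform(lo_deg, hi_deg))
    return length * np.array([np.cos(a), np.sin(a)])
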