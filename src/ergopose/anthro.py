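"""Anthropometric segment parameters.

The default table (``data/anthropometry.csv``) carries, per linkage segment,
its mass as a fraction of body mass, its length as a fraction of stature,
and its centre-of-mass location as a fraction of segment length from the
proximal end — values in the range reported by standard anthropometry
compilations (Winter-style segment parameter tables; Drillis-Contini length
ratios).  ``bilateral`` marks limb segments whose fraction is per side.

Mass fractions (counting bilateral segments twice) sum to 1.0: the whole
body is accounted for.  The table is overridable for non-default
populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass
class Anthropometry:
    """Segment parameter table scaled to one subject."""

    body_mass_kg: float
    stature_m: float
    segments: pd.DataFrame  # indexed by segment name

    def mass(self, segment: str, both_sides: bool = False) -> float:
        """Segment mass in kg; ``both_sides=True`` doubles bilateral segments."""
        row = self.segments.loc[segment]
        factor = 2.0 if (both_sides and row["bilateral"]) else 1.0
        return float(row["mass_fraction"]) * self.body_mass_kg * factor

    def length(self, segment: str) -> float:
        """Segment length in metres."""
        return float(self.segments.loc[segment, "length_fraction"]) * self.stature_m

    def com_fraction(self, segment: str) -> float:
        return float(self.segments.loc[segment, "com_fraction_from_proximal"])


def load_segment_table(path=None) -> pd.DataFrame:
    if path is None:
        with resources.files("ergopose.data").joinpath("anthropometry.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    df = df.set_index("segment")
    fr = df["mass_fraction"]
    if not ((fr > 0) & (fr < 1)).all():
        raise ValueError("segment mass fractions must lie in (0, 1)")
    total = float((fr * (1 + df["bilateral"])).sum())
    if total > 1.0 + 1e-9:
        raise ValueError(f"segment mass fractions sum to {total} > 1")
    return df


def default_anthropometry(
    body_mass_kg: float, stature_m: float, table_path=None
) -> Anthropometry:
    """Scale the configured segment-parameter table to a subject.

    Segment masses are ``fraction x body mass`` and lengths
    ``fraction x stature``.
    """
    if body_mass_kg <= 0 or stature_m <= 0:
        raise ValueError("body mass and stature must be positive")
    return Anthropometry(
        body_mass_kg=float(body_mass_kg),
        stature_m=float(stature_m),
        segments=load_segment_table(table_path),
    )
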