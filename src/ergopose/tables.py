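"""Loader for the versioned RULA/REBA scoring-table data files."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import TableLookupError


def _bin_score(angle: float, bins: list[list[float]]) -> int:
    """Score an angle against half-open bins [lower, upper)."""
    for lo, hi, score in bins:
        if lo <= angle < hi:
            return int(score)
    raise TableLookupError(f"angle {angle} matched no bin")  # pragma: no cover


class ScoringTables:
    """Parsed contents of one method's YAML table file."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.method: str = raw["method"]
        self.version: str = str(raw["version"])
        self.bins: dict = raw["bins"]
        self.cues: dict = raw["cues"]
        self.risk_bands: dict[str, tuple[int, int]] = {
            level: (int(lo), int(hi)) for level, (lo, hi) in raw["risk_bands"].items()
        }

    def bin(self, region: str, angle_deg: float) -> int:
        return _bin_score(float(angle_deg), self.bins[region])

    def risk_level(self, grand: int) -> str:
        for level, (lo, hi) in self.risk_bands.items():
            if lo <= grand <= hi:
                return level
        raise TableLookupError(
            f"{self.method} grand score {grand} outside every risk band"
        )

    @staticmethod
    def _lookup(table, indices: tuple[int, ...], what: str) -> int:
        node = table
        for i in indices:
            if not 1 <= i <= len(node):
                raise TableLookupError(
                    f"{what}: index {i} outside table domain 1..{len(node)} "
                    f"(indices {indices})"
                )
            node = node[i - 1]
        return int(node)


@lru_cache(maxsize=None)
def load_tables(method: str) -> ScoringTables:
    """Load the shipped tables for ``"rula"`` or ``"reba"``."""
    name = f"{method.lower()}_tables.yaml"
    with resources.files("ergopose.data").joinpath(name).open() as fh:
        return ScoringTables(yaml.safe_load(fh))
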