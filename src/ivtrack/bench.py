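"""Closed-form bench calculations: CTL cytotoxicity and caliper tumor volume."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class CytotoxicityInput:
    """Dead-target-cell fractions (0–1) from a CFSE/PI killing assay.

    ``experimental`` is the dead fraction with effectors present,
    ``spontaneous`` the dead fraction of targets alone.  The spontaneous
    fraction must be < 1 so the denominator is positive.
    """

    experimental_dead_fraction: float
    spontaneous_dead_fraction: float

    def __post_init__(self) -> None:
        e, s = self.experimental_dead_fraction, self.spontaneous_dead_fraction
        if not (0.0 <= e <= 1.0) or not math.isfinite(e):
            raise DomainError("experimental dead fraction must lie in [0, 1]")
        if not (0.0 <= s < 1.0) or not math.isfinite(s):
            raise DomainError("spontaneous dead fraction must lie in [0, 1)")


def cytotoxicity_percent(inputs: CytotoxicityInput) -> float:
    """Specific lysis: 100 · (experimental − spontaneous) / (1 − spontaneous).

    May be negative when fewer targets died with effectors present than
    spontaneously; the value is reported as-is so the caller can flag it.
    """
    e = inputs.experimental_dead_fraction
    s = inputs.spontaneous_dead_fraction
    return 100.0 * (e - s) / (1.0 - s)


@dataclass(frozen=True)
class TumorDims:
    """Caliper measurements in mm, all positive."""

    length_mm: float
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "height_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be a positive finite value")


def tumor_volume(dims: TumorDims) -> float:
    """Ellipsoid-style caliper volume V = L·W·H / 2, in mm³."""
    return dims.length_mm * dims.width_mm * dims.height_mm / 2.0
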