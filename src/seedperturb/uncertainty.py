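"""Uncertainty arithmetic: quadrature combination and replicate standard error.

Named relative standard uncertainty components (all in %, k = 1) combine as
the square root of the sum of squares.  Rounding is half-up to one decimal
and happens only at presentation; the raw combined value is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .dose_map import DoseMapError, DoseProfile, _GRID_ATOL

__all__ = [
    "UncertaintyBudget",
    "combine_quadrature",
    "round_half_up",
    "replicate_standard_error",
]


def combine_quadrature(components: Sequence[float]) -> float:
    """sqrt(sum of squares) of non-negative components (%, k = 1)."""
    vals = [float(c) for c in components]
    for c in vals:
        if c < 0:
            raise ValueError(f"uncertainty components must be >= 0, got {c}")
    return math.sqrt(sum(c * c for c in vals))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up decimal rounding for presentation (2.25 -> 2.3 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class UncertaintyBudget:
    """Named components plus their quadrature combination."""

    components: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for name, value in self.components:
            if value < 0:
                raise ValueError(f"component {name!r} is negative: {value}")

    @property
    def combined(self) -> float:
        return combine_quadrature([v for _, v in self.components])

    @property
    def combined_rounded(self) -> float:
        return round_half_up(self.combined, 1)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("component,value_percent\r\n")
            for name, value in self.components:
                fh.write(f"{name},{value:.17g}\r\n")
            fh.write(f"combined_k1,{self.combined:.17g}\r\n")

    @classmethod
    def from_csv(cls, path) -> "UncertaintyBudget":
        components = []
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("component"):
                raise ValueError("budget CSV must start with a component header row")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, value = line.rsplit(",", 1)
                if name == "combined_k1":
                    continue
                components.append((name, float(value)))
        return cls(components=components)


def replicate_standard_error(
    profiles: Sequence[DoseProfile],
    region: tuple[float, float] | None = None,
) -> float:
    """Per-position standard error of the mean across replicate profiles,
    as % of the per-position mean, averaged over a region.

    ``region`` is an inclusive ``(x_lo, x_hi)`` interval in mm; the default
    uses the whole shared extent.  Replicates must share position grids.
    """
    if len(profiles) < 2:
        raise ValueError(f"need >=2 replicate profiles, got {len(profiles)}")
    base = profiles[0]
    for p in profiles[1:]:
        if len(p) != len(base) or np.any(np.abs(p.positions - base.positions) > _GRID_ATOL):
            raise DoseMapError("replicate profiles must share the same position grid")
    stack = np.vstack([p.values for p in profiles])
    x = base.positions
    if region is not None:
        lo, hi = region
        mask = (x >= lo - _GRID_ATOL) & (x <= hi + _GRID_ATOL)
        if not np.any(mask):
            raise DoseMapError(f"region {region} lies outside profile extent [{x[0]}, {x[-1]}]")
        stack = stack[:, mask]
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if np.any(mean <= 0):
        raise DoseMapError("per-position mean must be > 0 to express SE in %")
    se = stack.std(axis=0, ddof=1) / math.sqrt(n)
    return float(np.mean(100.0 * se / mean))
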