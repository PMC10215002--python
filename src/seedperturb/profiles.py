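"""Profile-processing protocol: axis averaging, flat-area normalization,
the relative dose-change statistic, rebinning, and symmetrization.

The central quantity is the pointwise relative dose change between a seeded
and a reference acquisition,

    delta(x) = 100 * (seed(x) - ref(x)) / ref(x)   [%],

computed on matched position grids only (no silent interpolation).  Both
profiles are normalized to the mean of a flat band away from the field
center before differencing; the statistic is invariant under any common
rescaling of the pair, so normalization order does not matter for
proportional signals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dose_map import DoseMap, DoseMapError, DoseProfile, _GRID_ATOL

__all__ = [
    "PerturbationProfile",
    "axis_average",
    "normalize_to_flat",
    "delta_dose",
    "rebin",
    "crop",
    "symmetrize",
    "write_profile",
    "read_profile",
    "write_perturbation",
    "read_perturbation",
]

DEFAULT_FLAT_BAND = (40.0, 60.0)


@dataclass
class PerturbationProfile:
    """Signed relative dose change delta(x) in %, on a uniform grid."""

    positions: np.ndarray
    delta: np.ndarray
    bin: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.bin = float(self.bin)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise DoseMapError("perturbation positions must be a non-empty 1D array")
        if self.positions.shape != self.delta.shape:
            raise DoseMapError("positions and delta length mismatch")
        if not np.all(np.isfinite(self.delta)):
            raise DoseMapError("delta values must be finite")
        if self.positions.size > 1:
            steps = np.diff(self.positions)
            if np.any(np.abs(steps - self.bin) > _GRID_ATOL):
                raise DoseMapError("perturbation positions not uniform at stated bin")

    def __len__(self) -> int:
        return self.positions.size


def axis_average(
    dose_map: DoseMap,
    band_half_width_mm: float = 10.0,
    band_center_mm: float = 0.0,
) -> DoseProfile:
    """Average pixel rows inside ``|y - center| <= band_half_width`` per column.

    Collapses the in-plane (Y) direction to suppress scan and film
    nonuniformity, returning a cross-plane profile at the map's native x
    pitch.  ``band_center_mm`` lets cluster analyses take the band through
    a specific seed row.
    """
    if band_half_width_mm < 0:
        raise DoseMapError("band_half_width_mm must be >= 0")
    y = dose_map.y_coords
    mask = np.abs(y - band_center_mm) <= band_half_width_mm + _GRID_ATOL
    if not np.any(mask):
        raise DoseMapError(
            f"averaging band |y - {band_center_mm}| <= {band_half_width_mm} mm "
            f"contains no pixel rows (y extent [{y[0]}, {y[-1]}] mm)"
        )
    values = dose_map.values[mask, :].mean(axis=0)
    return DoseProfile(
        positions=dose_map.x_coords.copy(),
        values=values,
        bin=dose_map.spacing[0],
    )


def normalize_to_flat(
    profile: DoseProfile,
    flat_band: tuple[float, float] = DEFAULT_FLAT_BAND,
) -> DoseProfile:
    """Scale so the flat band (``inner <= |x| <= outer``) averages 100%.

    Default band 40-60 mm from field center, both sides pooled; each side
    must contribute at least 2 samples and the pooled mean must be > 0.
    """
    inner, outer = float(flat_band[0]), float(flat_band[1])
    if not 0 <= inner < outer:
        raise DoseMapError(f"invalid flat band {flat_band}")
    x = profile.positions
    in_band = (np.abs(x) >= inner - _GRID_ATOL) & (np.abs(x) <= outer + _GRID_ATOL)
    left = in_band & (x < 0)
    right = in_band & (x > 0)
    if left.sum() < 2 or right.sum() < 2:
        raise DoseMapError(
            f"flat band {inner}-{outer} mm needs >=2 samples per side "
            f"(got {int(left.sum())} left, {int(right.sum())} right; "
            f"profile extent [{x[0]}, {x[-1]}] mm)"
        )
    flat_mean = profile.values[in_band].mean()
    if flat_mean <= 0:
        raise DoseMapError(f"flat-band mean must be > 0, got {flat_mean}")
    return DoseProfile(
        positions=x.copy(),
        values=profile.values * (100.0 / flat_mean),
        bin=profile.bin,
    )


def delta_dose(
    seed: DoseProfile,
    ref: DoseProfile,
    labels: dict | None = None,
) -> PerturbationProfile:
    """Pointwise relative dose change 100*(seed - ref)/ref on matched grids.

    Positive values are build-up, negative build-down.  Grids must agree
    exactly (bin and positions); a mismatch is an error, never silently
    interpolated.  Reference values must all be strictly positive.
    """
    if len(seed) != len(ref) or abs(seed.bin - ref.bin) > _GRID_ATOL:
        raise DoseMapError(
            f"profile grids mismatch: seed has {len(seed)} pts at {seed.bin} mm, "
            f"ref has {len(ref)} pts at {ref.bin} mm"
        )
    if np.any(np.abs(seed.positions - ref.positions) > _GRID_ATOL):
        raise DoseMapError("profile position grids differ; rebin to a common grid first")
    bad = ref.values <= 0
    if np.any(bad):
        pos = ref.positions[bad][0]
        raise DoseMapError(f"reference value <= 0 at x = {pos} mm")
    delta = 100.0 * (seed.values - ref.values) / ref.values
    return PerturbationProfile(
        positions=ref.positions.copy(),
        delta=delta,
        bin=ref.bin,
        labels=dict(labels or {}),
    )


def _values_of(profile):
    return profile.delta if isinstance(profile, PerturbationProfile) else profile.values


def _rebuild(profile, positions, values):
    if isinstance(profile, PerturbationProfile):
        return PerturbationProfile(
            positions=positions,
            delta=values,
            bin=float(positions[1] - positions[0]) if positions.size > 1 else profile.bin,
            labels=dict(profile.labels),
        )
    return DoseProfile(
        positions=positions,
        values=values,
        bin=float(positions[1] - positions[0]) if positions.size > 1 else profile.bin,
    )


def rebin(profile, bin_mm: float = 0.1):
    """Resample onto a ``bin_mm``-pitch grid anchored so x = 0 is a node.

    Linear interpolation onto the lattice ``k * bin_mm`` restricted to the
    original extent; exact on linear data and value-preserving at original
    nodes that fall on the new lattice.  Works on dose and perturbation
    profiles alike.
    """
    bin_mm = float(bin_mm)
    if bin_mm <= 0:
        raise DoseMapError("bin_mm must be positive")
    x = profile.positions
    if x.size < 2:
        raise DoseMapError("rebin requires a profile with >=2 samples")
    lo, hi = x[0], x[-1]
    if bin_mm > hi - lo:
        raise DoseMapError(
            f"bin {bin_mm} mm exceeds profile extent {hi - lo} mm"
        )
    k_lo = int(np.ceil(lo / bin_mm - 1e-9))
    k_hi = int(np.floor(hi / bin_mm + 1e-9))
    new_x = np.arange(k_lo, k_hi + 1) * bin_mm
    new_v = np.interp(new_x, x, _values_of(profile))
    return _rebuild(profile, new_x, new_v)


def crop(profile, lo_mm: float, hi_mm: float):
    """Restrict a profile to positions in [lo_mm, hi_mm] (inclusive)."""
    x = profile.positions
    mask = (x >= lo_mm - _GRID_ATOL) & (x <= hi_mm + _GRID_ATOL)
    if not np.any(mask):
        raise DoseMapError(
            f"crop window [{lo_mm}, {hi_mm}] mm outside profile extent "
            f"[{x[0]}, {x[-1]}] mm"
        )
    return _rebuild(profile, x[mask].copy(), _values_of(profile)[mask].copy())


def symmetrize(profile):
    """Replace value(x) with the mirror mean (value(x) + value(-x)) / 2.

    Requires a symmetric position grid; idempotent.
    """
    x = profile.positions
    if np.any(np.abs(x + x[::-1]) > _GRID_ATOL):
        raise DoseMapError(
            f"cannot symmetrize: position grid [{x[0]}, {x[-1]}] mm is not "
            "symmetric about 0"
        )
    v = _values_of(profile)
    return _rebuild(profile, x.copy(), 0.5 * (v + v[::-1]))


def write_profile(profile: DoseProfile, path: str | os.PathLike) -> None:
    """2-column CSV: position_mm, value."""
    with open(Path(path), "w", newline="") as fh:
        fh.write("position_mm,value\r\n")
        for p, v in zip(profile.positions, profile.values):
            fh.write(f"{p:.17g},{v:.17g}\r\n")


def read_profile(path: str | os.PathLike) -> DoseProfile:
    data = np.genfromtxt(Path(path), delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    positions = data[:, 0]
    if positions.size < 2:
        raise DoseMapError("profile file must contain >=2 rows")
    return DoseProfile(positions=positions, values=data[:, 1], bin=positions[1] - positions[0])


def write_perturbation(profile: PerturbationProfile, path: str | os.PathLike) -> None:
    """3-column CSV: position_mm, delta_percent, flag."""
    flag = profile.labels.get("flag", 0)
    with open(Path(path), "w", newline="") as fh:
        fh.write("position_mm,delta_percent,flag\r\n")
        for p, v in zip(profile.positions, profile.delta):
            fh.write(f"{p:.17g},{v:.17g},{flag}\r\n")


def read_perturbation(path: str | os.PathLike) -> PerturbationProfile:
    data = np.genfromtxt(Path(path), delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    positions = data[:, 0]
    if positions.size < 2:
        raise DoseMapError("perturbation file must contain >=2 rows")
    return PerturbationProfile(
        positions=positions, delta=data[:, 1], bin=positions[1] - positions[0]
    )
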