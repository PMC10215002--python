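"""Multi-field rotational superposition of perturbation maps.

Rotational delivery is modelled phenomenologically: a single-field map is
rotated about the isocenter and the weighted copies are summed.  Localized
single-signed perturbations that are anisotropic about the isocenter smear
toward their rotational average, which is how build-up / build-down
features cancel under many beam directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .dose_map import DoseMap, DoseMapError
from .peaks import PeakModel
from .synthetic import SeedLayout, inject_perturbations, make_flat_field

__all__ = [
    "RotationPlan",
    "rotate_map",
    "superpose_fields",
    "residual_perturbation",
    "standard_dipole_scene",
]


@dataclass
class RotationPlan:
    """Field angles (degrees) and non-negative weights summing to 1."""

    n_fields: int
    angles: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise DoseMapError("n_fields must be >= 1")
        if self.angles is None:
            self.angles = np.arange(self.n_fields) * (360.0 / self.n_fields)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size != self.n_fields:
            raise DoseMapError("angles length must equal n_fields")
        reduced = np.sort(np.mod(self.angles, 360.0))
        if self.n_fields > 1 and np.any(np.diff(reduced) < 1e-9):
            raise DoseMapError("angles must be distinct modulo 360")
        if self.weights is None:
            self.weights = np.full(self.n_fields, 1.0 / self.n_fields)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != self.n_fields:
            raise DoseMapError("weights length must equal n_fields")
        if np.any(self.weights < 0):
            raise DoseMapError("weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DoseMapError(f"weights must sum to 1, got {self.weights.sum()}")


def _require_rotatable(dose_map: DoseMap) -> None:
    ny, nx = dose_map.shape
    if nx != ny:
        raise DoseMapError("rotation requires a square grid")
    if abs(dose_map.spacing[0] - dose_map.spacing[1]) > 1e-12:
        raise DoseMapError("rotation requires isotropic pixel spacing")
    x = dose_map.x_coords
    y = dose_map.y_coords
    if abs(x[0] + x[-1]) > 1e-9 or abs(y[0] + y[-1]) > 1e-9:
        raise DoseMapError("rotation requires the isocenter at the grid center")


def rotate_map(dose_map: DoseMap, angle_deg: float) -> tuple[DoseMap, bool]:
    """Rotate about the isocenter with bilinear resampling.

    Returns the rotated map and a flag that is True when any sampled source
    coordinate fell outside the grid while the grid boundary carries
    non-negligible signal (i.e. support was clipped).
    """
    _require_rotatable(dose_map)
    n = dose_map.shape[0]
    c = (n - 1) / 2.0
    idx = np.arange(n) - c
    jj, ii = np.meshgrid(idx, idx, indexing="ij")  # jj: row offset, ii: col offset
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # sample the input at the inverse-rotated coordinate
    src_i = cos_t * ii + sin_t * jj + c
    src_j = -sin_t * ii + cos_t * jj + c
    values = map_coordinates(
        dose_map.values, [src_j, src_i], order=1, mode="constant", cval=0.0
    )
    out_of_bounds = (
        (src_i < -1e-9) | (src_i > n - 1 + 1e-9) | (src_j < -1e-9) | (src_j > n - 1 + 1e-9)
    )
    boundary = np.concatenate(
        [
            dose_map.values[0, :],
            dose_map.values[-1, :],
            dose_map.values[:, 0],
            dose_map.values[:, -1],
        ]
    )
    clipped = bool(np.any(out_of_bounds) and np.max(np.abs(boundary)) > 1e-9)
    return dose_map.replace(values=values), clipped


def superpose_fields(dose_map: DoseMap, plan: RotationPlan) -> DoseMap:
    """Weighted sum of the map rotated to each planned angle.

    If any rotation clips non-zero support, the result's meta carries
    ``clipped_warning: True``.
    """
    _require_rotatable(dose_map)
    total = np.zeros_like(dose_map.values)
    any_clipped = False
    for angle, weight in zip(plan.angles, plan.weights):
        if angle % 360.0 == 0.0:
            rotated, clipped = dose_map, False
        else:
            rotated, clipped = rotate_map(dose_map, angle)
        total += weight * rotated.values
        any_clipped = any_clipped or clipped
    out = dose_map.replace(values=total)
    out.meta["n_fields"] = plan.n_fields
    if any_clipped:
        out.meta["clipped_warning"] = True
    return out


def residual_perturbation(
    composite: DoseMap,
    ref: DoseMap,
    roi_half_width_mm: float,
) -> tuple[float, float]:
    """(mean, max) of |100*(composite - ref)/ref| over a centered square ROI."""
    if composite.shape != ref.shape or composite.spacing != ref.spacing or composite.origin != ref.origin:
        raise DoseMapError("composite and reference maps must share the same grid")
    x = ref.x_coords
    y = ref.y_coords
    mask = (np.abs(y)[:, None] <= roi_half_width_mm + 1e-9) & (
        np.abs(x)[None, :] <= roi_half_width_mm + 1e-9
    )
    if not np.any(mask):
        raise DoseMapError("ROI contains no pixels")
    r = ref.values[mask]
    if np.any(r <= 0):
        raise DoseMapError("reference values in the ROI must be > 0")
    dd = np.abs(100.0 * (composite.values[mask] - r) / r)
    return float(dd.mean()), float(dd.max())


def standard_dipole_scene(
    size_mm: float = 150.0,
    spacing_mm: float = 0.5,
    offset_mm: float = 5.0,
) -> tuple[DoseMap, DoseMap]:
    """Fixed anisotropic BU/BD fixture used for cancellation studies.

    A broad +10% build-up Gaussian sits at (+offset, 0) and a narrow -12%
    build-down at (-offset, 0) on a flat field; the unequal widths and
    amplitudes make per-site residuals mixed-sign, so angular smearing
    genuinely cancels rather than merely redistributing.
    Returns (reference field, perturbed field).
    """
    field_half_width = min(50.0, size_mm / 2.0 - 8.0)
    base = make_flat_field(
        size_mm=size_mm, spacing_mm=spacing_mm, field_half_width_mm=field_half_width
    )
    bu = PeakModel(f0=0.0, m=0.0, h_g=10.0, h_l=0.0, w_g=2.8, w_l=2.8, mu=0.0, sign=1)
    bd = PeakModel(f0=0.0, m=0.0, h_g=12.0, h_l=0.0, w_g=1.4, w_l=1.4, mu=0.0, sign=-1)
    layout_bu = SeedLayout(positions=[(offset_mm, 0.0)])
    layout_bd = SeedLayout(positions=[(-offset_mm, 0.0)])
    perturbed = inject_perturbations(base, layout_bu, [bu], "BU")
    perturbed = inject_perturbations(perturbed, layout_bd, [bd], "BD")
    return base, perturbed
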