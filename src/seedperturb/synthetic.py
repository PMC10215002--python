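"""Synthetic dose-map generator with ground-truth perturbations.

Produces paired (reference, seeded) maps that emulate the measurement
scenes: a flat square field with penumbra, localized build-up (positive) or
build-down (negative) perturbations at single / 3x3 / 5x5 seed positions,
and multiplicative Gaussian pixel noise at the film-uncertainty level.
The recorded truth regenerates the noiseless seeded map bit-exactly, so
every downstream stage can be validated by parameter recovery.

Each seed's perturbation is a radially symmetric analogue of the 1D
composite peak: the cross-plane section through the seed center reproduces
the 1D truth exactly out to ``core_radius_mm``, beyond which a smooth
cosine taper brings it to zero at ``support_radius_mm``.  The compact
support keeps seeds in a cluster from contaminating each other's fit
windows; truth comparisons use the profile through the seed row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_map import DoseMap, DoseMapError
from .peaks import PeakModel, fwhm, perturbation_term

__all__ = [
    "SeedLayout",
    "SyntheticScene",
    "make_flat_field",
    "inject_perturbations",
    "add_noise",
    "make_scene",
    "draw_truth",
    "truth_frame",
]

_PATTERN_COUNTS = {"single": 1, "grid3x3": 9, "grid5x5": 25}

# default compact support of the injected footprint: exact composite shape
# out to CORE (covers the +/-2.5 mm fit window plus the 1 mm center bound),
# zero beyond SUPPORT
CORE_RADIUS_MM = 3.5
SUPPORT_RADIUS_MM = 5.0


@dataclass
class SeedLayout:
    """Seed center positions in the map plane.

    ``pattern`` is one of single / grid3x3 / grid5x5 / custom; grids are
    square with ``pitch`` mm between neighbours, centered on the origin.
    """

    positions: list[tuple[float, float]]
    pattern: str = "custom"
    pitch: float | None = None

    def __post_init__(self) -> None:
        self.positions = [(float(x), float(y)) for x, y in self.positions]
        expected = _PATTERN_COUNTS.get(self.pattern)
        if expected is not None and len(self.positions) != expected:
            raise DoseMapError(
                f"pattern {self.pattern!r} requires {expected} seeds, "
                f"got {len(self.positions)}"
            )
        if len(set(self.positions)) != len(self.positions):
            raise DoseMapError("duplicate seed positions")

    @classmethod
    def single(cls, position: tuple[float, float] = (0.0, 0.0)) -> "SeedLayout":
        return cls(positions=[position], pattern="single")

    @classmethod
    def grid(cls, n: int, pitch: float = 5.0) -> "SeedLayout":
        """n x n grid centered at the origin; n = 3 or 5 for the named patterns."""
        offsets = (np.arange(n) - (n - 1) / 2.0) * pitch
        positions = [(float(x), float(y)) for y in offsets for x in offsets]
        pattern = f"grid{n}x{n}" if n in (3, 5) else "custom"
        return cls(positions=positions, pattern=pattern, pitch=float(pitch))


def make_flat_field(
    size_mm: float,
    spacing_mm: float,
    field_half_width_mm: float = 50.0,
    penumbra_mm: float = 3.0,
    dose: float = 100.0,
) -> DoseMap:
    """Square flat-top field centered on the isocenter.

    The plateau sits exactly at ``dose``; each edge falls to zero over a
    ``penumbra_mm``-wide cosine ramp (exact plateau / exact zero outside,
    so flat-region means are exact).  ``penumbra_mm = 0`` gives a hard
    step.  The grid is odd-sized so (0, 0) is a pixel center.
    """
    spacing_mm = float(spacing_mm)
    if spacing_mm <= 0:
        raise DoseMapError("spacing_mm must be positive")
    if penumbra_mm < 0:
        raise DoseMapError("penumbra_mm must be >= 0")
    if field_half_width_mm + penumbra_mm / 2.0 > size_mm / 2.0:
        raise DoseMapError(
            f"field (half-width {field_half_width_mm} mm + penumbra) does not fit "
            f"inside a {size_mm} mm grid"
        )
    half_n = int(np.floor((size_mm / 2.0) / spacing_mm + 1e-9))
    coords = (np.arange(2 * half_n + 1) - half_n) * spacing_mm

    def edge(c: np.ndarray) -> np.ndarray:
        t = np.abs(c) - field_half_width_mm
        if penumbra_mm == 0:
            return np.where(t <= 0, 1.0, 0.0)
        u = t / penumbra_mm
        ramp = 0.5 - 0.5 * np.sin(np.pi * np.clip(u, -0.5, 0.5))
        return np.where(u <= -0.5, 1.0, np.where(u >= 0.5, 0.0, ramp))

    fx = edge(coords)
    fy = edge(coords)
    values = dose * np.outer(fy, fx)
    return DoseMap(
        values=values,
        spacing=(spacing_mm, spacing_mm),
        origin=(float(coords[0]), float(coords[0])),
        meta={"field_half_width_mm": field_half_width_mm, "penumbra_mm": penumbra_mm},
    )


def _taper(r: np.ndarray, core: float, support: float) -> np.ndarray:
    if support <= core:
        raise DoseMapError("support_radius_mm must exceed core_radius_mm")
    u = (r - core) / (support - core)
    w = 0.5 + 0.5 * np.cos(np.pi * np.clip(u, 0.0, 1.0))
    return np.where(r <= core, 1.0, np.where(r >= support, 0.0, w))


def inject_perturbations(
    dose_map: DoseMap,
    layout: SeedLayout,
    truth: Sequence[PeakModel],
    plane: str,
    core_radius_mm: float = CORE_RADIUS_MM,
    support_radius_mm: float | None = SUPPORT_RADIUS_MM,
) -> DoseMap:
    """Add per-seed radially symmetric perturbations; contributions sum.

    ``plane`` selects the sign: "BU" adds, "BD" subtracts.  Each seed's
    cross-plane section through its own center equals the 1D composite term
    of its :class:`PeakModel` out to ``core_radius_mm`` (further tapered to
    zero at ``support_radius_mm``; pass ``support_radius_mm=None`` for the
    untruncated shape).  Seed centers must lie inside the grid.
    """
    if plane not in ("BU", "BD"):
        raise DoseMapError(f"plane must be 'BU' or 'BD', got {plane!r}")
    if len(truth) != len(layout.positions):
        raise DoseMapError(
            f"truth has {len(truth)} models for {len(layout.positions)} seeds"
        )
    sign = 1.0 if plane == "BU" else -1.0
    x = dose_map.x_coords
    y = dose_map.y_coords
    for sx, sy in layout.positions:
        if not (x[0] <= sx <= x[-1] and y[0] <= sy <= y[-1]):
            raise DoseMapError(f"seed at ({sx}, {sy}) mm lies outside the grid")
    xx, yy = np.meshgrid(x, y)
    out = dose_map.values.copy()
    for (sx, sy), model in zip(layout.positions, truth):
        r = np.hypot(xx - sx, yy - sy)
        centered = PeakModel(
            f0=0.0, m=model.m, h_g=model.h_g, h_l=model.h_l,
            w_g=model.w_g, w_l=model.w_l, mu=0.0, sign=model.sign,
        )
        pert = perturbation_term(centered, r)
        if support_radius_mm is not None:
            pert = pert * _taper(r, core_radius_mm, support_radius_mm)
        out += sign * pert
    return dose_map.replace(values=out)


def add_noise(dose_map: DoseMap, sd_percent: float, rng_seed) -> DoseMap:
    """Independent zero-mean Gaussian noise, per-pixel SD = sd% of the value.

    Deterministic for a given ``rng_seed`` (int, SeedSequence, or Generator).
    """
    if sd_percent < 0:
        raise DoseMapError("sd_percent must be >= 0")
    if sd_percent == 0:
        return dose_map.replace()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    noise = rng.standard_normal(dose_map.values.shape)
    values = dose_map.values * (1.0 + (sd_percent / 100.0) * noise)
    return dose_map.replace(values=values)


@dataclass
class SyntheticScene:
    """Full configuration of a paired (reference, seeded) acquisition."""

    layout: SeedLayout
    truth: list[PeakModel]
    plane: str = "BU"
    size_mm: float = 130.0
    spacing_mm: float = 0.25
    field_half_width_mm: float = 50.0
    penumbra_mm: float = 3.0
    dose: float = 100.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    core_radius_mm: float = CORE_RADIUS_MM
    support_radius_mm: float | None = SUPPORT_RADIUS_MM
    meta: dict = field(default_factory=dict)


def make_scene(scene: SyntheticScene) -> tuple[DoseMap, DoseMap, pd.DataFrame]:
    """Generate (ref, seeded, truth record) for a scene.

    ref = flat field + noise; seeded = flat field + perturbations +
    independent noise.  Both noise streams derive deterministically from
    ``scene.rng_seed``.
    """
    base = make_flat_field(
        size_mm=scene.size_mm,
        spacing_mm=scene.spacing_mm,
        field_half_width_mm=scene.field_half_width_mm,
        penumbra_mm=scene.penumbra_mm,
        dose=scene.dose,
    )
    seeded_clean = inject_perturbations(
        base,
        scene.layout,
        scene.truth,
        scene.plane,
        core_radius_mm=scene.core_radius_mm,
        support_radius_mm=scene.support_radius_mm,
    )
    ss_ref, ss_seed = np.random.SeedSequence(scene.rng_seed).spawn(2)
    ref = add_noise(base, scene.noise_sd, ss_ref)
    seeded = add_noise(seeded_clean, scene.noise_sd, ss_seed)
    ref.meta.update(scene.meta, plane=scene.plane, role="reference")
    seeded.meta.update(scene.meta, plane=scene.plane, role="seeded")
    return ref, seeded, truth_frame(scene)


def truth_frame(scene: SyntheticScene) -> pd.DataFrame:
    """Per-seed ground-truth table (one row per seed)."""
    rows = []
    sign = 1 if scene.plane == "BU" else -1
    for i, ((sx, sy), m) in enumerate(zip(scene.layout.positions, scene.truth)):
        amp = m.a_g + m.a_l
        rows.append(
            {
                "seed": i,
                "x_mm": sx,
                "y_mm": sy,
                "plane": scene.plane,
                "sign": sign,
                "amplitude_percent": sign * amp,
                "M": m.m,
                "A_G": m.a_g,
                "A_L": m.a_l,
                "W_G_mm": m.w_g,
                "W_L_mm": m.w_l,
                "fwhm_mm": fwhm(m) if amp > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def draw_truth(
    rng: np.random.Generator,
    n_seeds: int,
    amplitude_range: tuple[float, float] = (5.0, 15.0),
    width_range: tuple[float, float] = (0.5, 2.2),
    m_range: tuple[float, float] = (0.0, 1.0),
    sign: int = 1,
) -> list[PeakModel]:
    """Random in-bounds truth models (amplitudes in %, widths = FWHM in mm).

    Default ranges follow the measured build-up regime; pass ``sign=-1``
    and e.g. ``amplitude_range=(8, 23)`` for build-down scenes.
    """
    models = []
    for _ in range(n_seeds):
        amp = rng.uniform(*amplitude_range)
        m = rng.uniform(*m_range)
        models.append(
            PeakModel(
                f0=0.0,
                m=m,
                h_g=amp,
                h_l=amp,
                w_g=rng.uniform(*width_range),
                w_l=rng.uniform(*width_range),
                mu=0.0,
                sign=sign,
            )
        )
    return models
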