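"""Data model and I/O for 2D dose maps and 1D dose profiles.

A :class:`DoseMap` is a rectangular grid of dose (or raw scanner signal)
values with a physical pixel pitch and an origin expressed relative to the
beam central axis.  Coordinates follow a pixel-center convention: pixel
``(i, j)`` (column ``i``, row ``j``, both 0-based) sits at
``(x0 + i*dx, y0 + j*dy)`` in millimetres, with the isocenter projection
at ``(0, 0)``.

Maps round-trip through two plain-text formats (whitespace matrix and CSV)
and can be loaded from baseline RGB TIFF scans, in which case a single
colour channel is extracted as the value grid.  No dose calibration is
applied on load; raw signal passes through untouched.  An optional
monotonic calibration table can be applied explicitly via
:func:`apply_calibration`.
"""

from __future__ import annotations

import csv as _csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DoseMap",
    "DoseProfile",
    "DoseMapError",
    "ParseError",
    "read_dose_map",
    "write_dose_map",
    "crop_to_field",
    "apply_calibration",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}

# position grid uniformity / symmetry comparisons
_GRID_ATOL = 1e-9


class DoseMapError(ValueError):
    """Invalid dose-map or profile construction or operation."""


class ParseError(DoseMapError):
    """A text dose-map file could not be parsed."""


@dataclass
class DoseMap:
    """2D dose grid with physical pixel spacing and origin.

    Parameters
    ----------
    values:
        2D array, shape ``(ny, nx)``; ``values[j, i]`` is the dose (or raw
        signal) at ``(x0 + i*dx, y0 + j*dy)``.
    spacing:
        ``(dx, dy)`` pixel pitch in mm, both strictly positive.
    origin:
        ``(x0, y0)`` position in mm of pixel ``(0, 0)``'s center relative
        to the beam central axis.
    meta:
        Free-form tags (energy label, seed model, plane, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DoseMapError(
                f"dose map must be a non-empty 2D grid, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            j, i = np.argwhere(~np.isfinite(self.values))[0]
            raise DoseMapError(f"non-finite value at pixel (i={i}, j={j})")
        dx, dy = (float(self.spacing[0]), float(self.spacing[1]))
        if not (dx > 0 and dy > 0):
            raise DoseMapError(f"spacing must be strictly positive, got {self.spacing}")
        self.spacing = (dx, dy)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) grid shape."""
        return self.values.shape

    @property
    def x_coords(self) -> np.ndarray:
        """x (cross-plane) pixel-center coordinates, mm."""
        return self.origin[0] + np.arange(self.shape[1]) * self.spacing[0]

    @property
    def y_coords(self) -> np.ndarray:
        """y (in-plane) pixel-center coordinates, mm."""
        return self.origin[1] + np.arange(self.shape[0]) * self.spacing[1]

    def pixel_coord(self, i: int, j: int) -> tuple[float, float]:
        """Physical (x, y) of pixel-center (column i, row j)."""
        return (
            self.origin[0] + i * self.spacing[0],
            self.origin[1] + j * self.spacing[1],
        )

    def replace(self, **kwargs) -> "DoseMap":
        """Copy with selected fields replaced."""
        data = {
            "values": self.values.copy(),
            "spacing": self.spacing,
            "origin": self.origin,
            "meta": dict(self.meta),
        }
        data.update(kwargs)
        return DoseMap(**data)


@dataclass
class DoseProfile:
    """1D uniformly spaced cross-plane dose profile.

    ``positions`` are strictly increasing, uniformly spaced x in mm (0 at
    field center); ``values`` carry dose in % (or raw signal); ``bin`` is
    the spacing in mm.
    """

    positions: np.ndarray
    values: np.ndarray
    bin: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.bin = float(self.bin)
        if self.positions.ndim != 1 or self.positions.size == 0:
            raise DoseMapError("profile positions must be a non-empty 1D array")
        if self.positions.shape != self.values.shape:
            raise DoseMapError(
                f"positions ({self.positions.shape}) and values "
                f"({self.values.shape}) length mismatch"
            )
        if not np.all(np.isfinite(self.values)):
            raise DoseMapError("profile values must be finite")
        if self.positions.size > 1:
            steps = np.diff(self.positions)
            if np.any(np.abs(steps - self.bin) > _GRID_ATOL):
                raise DoseMapError(
                    "profile positions are not uniformly spaced at the stated bin"
                )

    def __len__(self) -> int:
        return self.positions.size


def _parse_sidecar_line(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if not body:
        return
    parts = body.split(None, 1)
    if len(parts) == 2:
        key, value = parts
        try:
            meta[key] = float(value)
        except ValueError:
            meta[key] = value
    else:
        meta[parts[0]] = True


def _rows_to_grid(rows: list[list[str]], path: str | os.PathLike) -> np.ndarray:
    if not rows:
        raise ParseError(f"{path}: no data rows")
    width = len(rows[0])
    grid = np.empty((len(rows), width), dtype=float)
    for j, row in enumerate(rows):
        if len(row) != width:
            raise ParseError(
                f"{path}: non-rectangular matrix (row {j + 1} has {len(row)} "
                f"columns, expected {width})"
            )
        for i, cell in enumerate(row):
            try:
                grid[j, i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {j + 1}, "
                    f"column {i + 1}"
                ) from None
    return grid


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".csv":
        return "csv"
    return "matrix-text"


def read_dose_map(
    path: str | os.PathLike,
    format: str | None = None,
    channel: str | None = None,
    spacing: tuple[float, float] | None = None,
    origin: tuple[float, float] | None = None,
    meta: Mapping | None = None,
) -> DoseMap:
    """Load a dose map from matrix-text, CSV, or TIFF.

    Text formats may carry ``dx``/``dy``/``x0``/``y0`` in ``#``-prefixed
    sidecar header lines (matrix-text: inline; CSV: companion ``<path>.meta``
    file).  Explicit ``spacing``/``origin`` arguments override the sidecar.
    For TIFF, ``channel`` selects one plane of an RGB scan ("red" for the
    film protocol); raw signal is returned with no calibration applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dose map file not found: {path}")
    fmt = format or _infer_format(path)
    sidecar: dict = {}

    if fmt == "matrix-text":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    _parse_sidecar_line(line, sidecar)
                else:
                    rows.append(line.split())
        values = _rows_to_grid(rows, path)
    elif fmt == "csv":
        with open(path, newline="") as fh:
            rows = [row for row in _csv.reader(fh) if row and any(c.strip() for c in row)]
        values = _rows_to_grid(rows, path)
        meta_path = path.with_name(path.name + ".meta")
        if meta_path.exists():
            with open(meta_path) as fh:
                for line in fh:
                    if line.strip():
                        _parse_sidecar_line(line, sidecar)
    elif fmt == "tiff":
        import tifffile

        arr = np.asarray(tifffile.imread(path))
        if channel is not None and channel != "none":
            if channel not in _CHANNELS:
                raise DoseMapError(f"unknown channel {channel!r}")
            if arr.ndim != 3 or arr.shape[-1] < 3:
                raise DoseMapError(
                    f"channel {channel!r} requested but image has shape "
                    f"{arr.shape} (needs >=3 channels)"
                )
            values = arr[..., _CHANNELS[channel]].astype(float)
        else:
            if arr.ndim != 2:
                raise DoseMapError(
                    f"multi-channel image (shape {arr.shape}) requires a channel"
                )
            values = arr.astype(float)
    else:
        raise DoseMapError(f"unknown format {fmt!r}")

    dx = sidecar.pop("dx", 1.0)
    dy = sidecar.pop("dy", 1.0)
    x0 = sidecar.pop("x0", 0.0)
    y0 = sidecar.pop("y0", 0.0)
    if spacing is not None:
        dx, dy = spacing
    if origin is not None:
        x0, y0 = origin
    full_meta = dict(sidecar)
    if meta:
        full_meta.update(meta)
    return DoseMap(values=values, spacing=(dx, dy), origin=(x0, y0), meta=full_meta)


def write_dose_map(dose_map: DoseMap, path: str | os.PathLike, format: str | None = None) -> None:
    """Serialize a map to matrix-text or CSV at full decimal precision.

    Refuses non-finite values (error names the offending pixel) so that
    write -> read always round-trips bit-exactly on the value grid.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        raise DoseMapError("writing TIFF is not supported; use matrix-text or csv")
    values = dose_map.values
    if not np.all(np.isfinite(values)):
        j, i = np.argwhere(~np.isfinite(values))[0]
        raise DoseMapError(f"refusing to write non-finite value at pixel (i={i}, j={j})")

    header = [
        f"# dx {dose_map.spacing[0]:.17g}",
        f"# dy {dose_map.spacing[1]:.17g}",
        f"# x0 {dose_map.origin[0]:.17g}",
        f"# y0 {dose_map.origin[1]:.17g}",
    ]
    units = dose_map.meta.get("units")
    if units is not None:
        header.append(f"# units {units}")

    def fmt_row(row, sep):
        return sep.join(f"{v:.17g}" for v in row)

    if fmt == "matrix-text":
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for row in values:
                fh.write(fmt_row(row, " ") + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            for row in values:
                fh.write(fmt_row(row, ",") + "\r\n")
        with open(Path(path).with_name(Path(path).name + ".meta"), "w") as fh:
            fh.write("\n".join(header) + "\n")
    else:
        raise DoseMapError(f"unknown format {fmt!r}")


def crop_to_field(dose_map: DoseMap, half_width_mm: float) -> DoseMap:
    """Return the sub-grid of pixels with |x| <= half_width and |y| <= half_width.

    The requested window must lie inside the grid extent; the origin of the
    cropped map is updated so physical coordinates are unchanged.
    """
    hw = float(half_width_mm)
    if hw <= 0:
        raise DoseMapError("half_width_mm must be positive")
    x = dose_map.x_coords
    y = dose_map.y_coords
    # extent measured to pixel edges so that cropping is idempotent
    hx = dose_map.spacing[0] / 2.0
    hy = dose_map.spacing[1] / 2.0
    if x[0] - hx > -hw or x[-1] + hx < hw or y[0] - hy > -hw or y[-1] + hy < hw:
        raise DoseMapError(
            f"crop window +/-{hw} mm exceeds grid extent "
            f"x=[{x[0]}, {x[-1]}] mm, y=[{y[0]}, {y[-1]}] mm"
        )
    xi = np.where(np.abs(x) <= hw + _GRID_ATOL)[0]
    yi = np.where(np.abs(y) <= hw + _GRID_ATOL)[0]
    return DoseMap(
        values=dose_map.values[yi[0] : yi[-1] + 1, xi[0] : xi[-1] + 1].copy(),
        spacing=dose_map.spacing,
        origin=(float(x[xi[0]]), float(y[yi[0]])),
        meta=dict(dose_map.meta),
    )


def apply_calibration(
    dose_map: DoseMap,
    signal: Sequence[float],
    dose: Sequence[float],
) -> DoseMap:
    """Map raw scanner signal to dose via a monotonic lookup table.

    ``signal`` must be strictly monotonic; the table is linearly
    interpolated (and linearly extrapolated at the ends).  This is the only
    place any signal-to-dose conversion happens: readers always pass raw
    signal through.
    """
    sig = np.asarray(signal, dtype=float)
    dos = np.asarray(dose, dtype=float)
    if sig.size != dos.size or sig.size < 2:
        raise DoseMapError("calibration table needs >=2 matched (signal, dose) points")
    diffs = np.diff(sig)
    if np.all(diffs > 0):
        pass
    elif np.all(diffs < 0):
        sig, dos = sig[::-1], dos[::-1]
    else:
        raise DoseMapError("calibration signal values must be strictly monotonic")
    slope_lo = (dos[1] - dos[0]) / (sig[1] - sig[0])
    slope_hi = (dos[-1] - dos[-2]) / (sig[-1] - sig[-2])
    v = dose_map.values
    out = np.interp(v, sig, dos)
    out = np.where(v < sig[0], dos[0] + (v - sig[0]) * slope_lo, out)
    out = np.where(v > sig[-1], dos[-1] + (v - sig[-1]) * slope_hi, out)
    return dose_map.replace(values=out)
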