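"""Detector metrology for the 8-module stacked detector layout.

The detector consists of eight sensor modules of 512 (fast) x 1024 (slow)
pixels.  In memory the eight module panels are stacked along the slow axis
into a single (8192, 512) array.  Convention used throughout this package:

* panel arrays are indexed ``[slow, fast]`` (row-major),
* the stacked array has shape ``(8 * slow_extent, fast_extent)``;
  module ``m`` occupies rows ``m*slow_extent .. (m+1)*slow_extent - 1``,
* pixel indexing is 0-based with pixel centers at integer coordinates.

The stacked layout does not reflect the physical arrangement of the modules;
:func:`pixel_to_lab` and the ``.geom`` writer carry the metrology.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_MODULES = 8
FULL_FAST_EXTENT = 512
FULL_SLOW_EXTENT = 1024

#: default per-module gain in electrons per ADU (one 7300 eV photon = 2000 e-
#: = 200 ADU), chosen so the raw 16-bit range spans ~325 photons per pixel.
DEFAULT_GAIN_E_PER_ADU = 10.0
DEFAULT_PIXEL_SIZE_MM = 0.05
DEFAULT_CAMERA_LENGTH_MM = 50.0


class GeometryError(ValueError):
    """Raised for invalid detector geometry definitions."""


def _unit(v: Sequence[float]) -> tuple[float, float]:
    x, y = float(v[0]), float(v[1])
    n = math.hypot(x, y)
    if n == 0:
        raise GeometryError("axis vector must be non-zero")
    return (x, y)


@dataclasses.dataclass(frozen=True)
class ModulePanel:
    """One sensor module: extents, lab-frame origin and axes.

    ``origin_lab`` is the lab-frame (x, y) position in mm of the center of
    pixel (fast=0, slow=0).  ``fast_axis``/``slow_axis`` are unit vectors in
    the lab frame; one pixel step along fast moves by
    ``pixel_size * fast_axis`` mm.
    """

    index: int
    fast_extent: int = FULL_FAST_EXTENT
    slow_extent: int = FULL_SLOW_EXTENT
    origin_lab: tuple[float, float] = (0.0, 0.0)
    fast_axis: tuple[float, float] = (1.0, 0.0)
    slow_axis: tuple[float, float] = (0.0, 1.0)
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        if self.fast_extent <= 0 or self.slow_extent <= 0:
            raise GeometryError("panel extents must be positive")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        fx, fy = _unit(self.fast_axis)
        sx, sy = _unit(self.slow_axis)
        if not math.isclose(math.hypot(fx, fy), 1.0, abs_tol=1e-6):
            raise GeometryError("fast_axis must be a unit vector")
        if not math.isclose(math.hypot(sx, sy), 1.0, abs_tol=1e-6):
            raise GeometryError("slow_axis must be a unit vector")
        if abs(fx * sx + fy * sy) > 1e-6:
            raise GeometryError("fast_axis and slow_axis must be orthogonal")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (slow, fast) of this panel."""
        return (self.slow_extent, self.fast_extent)


@dataclasses.dataclass(frozen=True)
class DetectorGeometry:
    """Eight module panels plus camera distance, beam center and gains."""

    panels: tuple[ModulePanel, ...]
    camera_length_mm: float = DEFAULT_CAMERA_LENGTH_MM
    beam_center_mm: tuple[float, float] = (0.0, 0.0)
    gains: tuple[float, ...] = (DEFAULT_GAIN_E_PER_ADU,) * N_MODULES

    def __post_init__(self) -> None:
        object.__setattr__(self, "panels", tuple(self.panels))
        object.__setattr__(self, "gains", tuple(float(g) for g in self.gains))
        if len(self.panels) != N_MODULES:
            raise GeometryError(
                f"expected {N_MODULES} panels, got {len(self.panels)}"
            )
        if len(self.gains) != N_MODULES:
            raise GeometryError(f"expected {N_MODULES} gains, got {len(self.gains)}")
        if any(g <= 0 for g in self.gains):
            raise GeometryError("gains must be positive")
        if self.camera_length_mm <= 0:
            raise GeometryError("camera_length_mm must be positive")
        ext = {(p.fast_extent, p.slow_extent) for p in self.panels}
        if len(ext) != 1:
            raise GeometryError("all panels must share the same extents")

    @property
    def fast_extent(self) -> int:
        return self.panels[0].fast_extent

    @property
    def slow_extent(self) -> int:
        return self.panels[0].slow_extent

    @property
    def pixel_size(self) -> float:
        return self.panels[0].pixel_size

    @property
    def panel_shape(self) -> tuple[int, int]:
        return self.panels[0].shape


def default_geometry(
    fast_extent: int = FULL_FAST_EXTENT,
    slow_extent: int = FULL_SLOW_EXTENT,
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM,
    camera_length_mm: float = DEFAULT_CAMERA_LENGTH_MM,
    gains: Sequence[float] | None = None,
) -> DetectorGeometry:
    """Default metrology: 8 panels stacked contiguously with no gaps,
    beam center at the center of the stacked array."""
    if gains is None:
        gains = (DEFAULT_GAIN_E_PER_ADU,) * N_MODULES
    rows = N_MODULES * slow_extent
    panels = tuple(
        ModulePanel(
            index=m,
            fast_extent=fast_extent,
            slow_extent=slow_extent,
            origin_lab=(
                -0.5 * fast_extent * pixel_size,
                (m * slow_extent - 0.5 * rows) * pixel_size,
            ),
            pixel_size=pixel_size,
        )
        for m in range(N_MODULES)
    )
    return DetectorGeometry(
        panels=panels,
        camera_length_mm=camera_length_mm,
        beam_center_mm=(0.0, 0.0),
        gains=tuple(float(g) for g in gains),
    )


def stacked_shape(geometry: DetectorGeometry) -> tuple[int, int]:
    """Shape (rows, cols) of the raw in-memory stacked array.

    Rows are the stacking dimension: ``8 * slow_extent`` (8192 for the
    full-size detector); columns are the fast extent (512).
    """
    return (N_MODULES * geometry.slow_extent, geometry.fast_extent)


def stacked_index(
    geometry: DetectorGeometry, module: int, fast: int, slow: int
) -> tuple[int, int]:
    """Map a (module, fast, slow) pixel to its (row, col) in the stacked array."""
    _check_pixel(geometry, module, fast, slow)
    return (module * geometry.slow_extent + slow, fast)


def unstack_index(geometry: DetectorGeometry, row: int, col: int) -> tuple[int, int, int]:
    """Inverse of :func:`stacked_index`: (row, col) -> (module, fast, slow)."""
    rows, cols = stacked_shape(geometry)
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"stacked index ({row}, {col}) outside {rows}x{cols}")
    module, slow = divmod(int(row), geometry.slow_extent)
    return (module, int(col), slow)


def stack_panels(panels: Sequence[np.ndarray]) -> np.ndarray:
    """Stack 8 panel arrays (slow, fast) vertically into one array."""
    if len(panels) != N_MODULES:
        raise GeometryError(f"expected {N_MODULES} panels, got {len(panels)}")
    return np.vstack(panels)


def split_stacked(geometry: DetectorGeometry, stacked: np.ndarray) -> list[np.ndarray]:
    """Split a stacked array back into the 8 panel views."""
    rows, cols = stacked_shape(geometry)
    if stacked.shape != (rows, cols):
        raise GeometryError(
            f"stacked array has shape {stacked.shape}, expected {(rows, cols)}"
        )
    s = geometry.slow_extent
    return [stacked[m * s : (m + 1) * s, :] for m in range(N_MODULES)]


def _check_pixel(geometry: DetectorGeometry, module: int, fast: int, slow: int) -> None:
    if not 0 <= module < N_MODULES:
        raise IndexError(f"module {module} out of range 0..{N_MODULES - 1}")
    p = geometry.panels[module]
    if not (0 <= fast < p.fast_extent and 0 <= slow < p.slow_extent):
        raise IndexError(
            f"pixel (fast={fast}, slow={slow}) outside panel "
            f"{p.fast_extent}x{p.slow_extent}"
        )


def pixel_to_lab(
    geometry: DetectorGeometry, module: int, fast: float, slow: float
) -> tuple[float, float]:
    """Lab-frame (x, y) in mm of a pixel center.

    ``position = origin + fast * fast_axis * pixel_size
                        + slow * slow_axis * pixel_size``
    """
    _check_pixel(geometry, module, int(fast), int(slow))
    p = geometry.panels[module]
    ox, oy = p.origin_lab
    fx, fy = p.fast_axis
    sx, sy = p.slow_axis
    x = ox + fast * fx * p.pixel_size + slow * sx * p.pixel_size
    y = oy + fast * fy * p.pixel_size + slow * sy * p.pixel_size
    return (x, y)


def panel_lab_grids(geometry: DetectorGeometry) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-panel (X, Y) lab-coordinate arrays in mm, shape (slow, fast)."""
    out = []
    for p in geometry.panels:
        fast = np.arange(p.fast_extent, dtype=np.float64)
        slow = np.arange(p.slow_extent, dtype=np.float64)
        F, S = np.meshgrid(fast, slow)  # (slow, fast)
        ox, oy = p.origin_lab
        fx, fy = p.fast_axis
        sx, sy = p.slow_axis
        X = ox + F * fx * p.pixel_size + S * sx * p.pixel_size
        Y = oy + F * fy * p.pixel_size + S * sy * p.pixel_size
        out.append((X, Y))
    return out


def panel_radius_maps(
    geometry: DetectorGeometry, center_mm: tuple[float, float] | None = None
) -> list[np.ndarray]:
    """Per-panel radial distance (in pixel units) from a lab-frame center."""
    if center_mm is None:
        center_mm = geometry.beam_center_mm
    cx, cy = center_mm
    maps = []
    for X, Y in panel_lab_grids(geometry):
        maps.append(np.hypot(X - cx, Y - cy) / geometry.pixel_size)
    return maps


# --------------------------------------------------------------------------
# .geom text file (CrystFEL-style key/value dialect)
# --------------------------------------------------------------------------

def _fmt_axis(ax: tuple[float, float]) -> str:
    return f"{ax[0]:+.9f}x {ax[1]:+.9f}y"


def write_geom_file(geometry: DetectorGeometry, path: str | Path) -> None:
    """Write a CrystFEL-geom-style text description of the geometry.

    Standard keys (clen, res, pN/min_fs .. pN/ss) are augmented with custom
    keys (pN/gain, beam_center_x_mm/y_mm) so that :func:`read_geom_file`
    reproduces every :class:`DetectorGeometry` field.
    """
    path = Path(path)
    lines = [
        "; detector geometry (stacked 8-module layout)",
        "; rows = stacking dimension (slow), cols = fast",
        f"clen = {geometry.camera_length_mm / 1000.0!r}",
        f"res = {1000.0 / geometry.pixel_size!r}",
        "photon_energy = /metadata/photon_energy_ev",
        f"beam_center_x_mm = {geometry.beam_center_mm[0]!r}",
        f"beam_center_y_mm = {geometry.beam_center_mm[1]!r}",
        "",
    ]
    bx, by = geometry.beam_center_mm
    for p in geometry.panels:
        m = p.index
        corner_x = (p.origin_lab[0] - bx) / p.pixel_size
        corner_y = (p.origin_lab[1] - by) / p.pixel_size
        lines += [
            f"p{m}/min_fs = 0",
            f"p{m}/max_fs = {p.fast_extent - 1}",
            f"p{m}/min_ss = {m * p.slow_extent}",
            f"p{m}/max_ss = {(m + 1) * p.slow_extent - 1}",
            f"p{m}/corner_x = {corner_x!r}",
            f"p{m}/corner_y = {corner_y!r}",
            f"p{m}/fs = {_fmt_axis(p.fast_axis)}",
            f"p{m}/ss = {_fmt_axis(p.slow_axis)}",
            f"p{m}/gain = {geometry.gains[m]!r}",
            "",
        ]
    path.write_text("\n".join(lines))


_AXIS_RE = re.compile(r"([+-]?[0-9.eE+-]+)x\s+([+-]?[0-9.eE+-]+)y")


def read_geom_file(path: str | Path) -> DetectorGeometry:
    """Parse a file written by :func:`write_geom_file`."""
    top: dict[str, str] = {}
    panel_kv: dict[int, dict[str, str]] = {}
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.split(";", 1)[0].strip()
        if not line or "=" not in line:
            continue
        key, value = (s.strip() for s in line.split("=", 1))
        m = re.match(r"^p(\d+)/(\w+)$", key)
        if m:
            panel_kv.setdefault(int(m.group(1)), {})[m.group(2)] = value
        else:
            top[key] = value

    pixel_size = 1000.0 / float(top["res"])
    camera_length_mm = round(float(top["clen"]) * 1000.0, 6)
    beam_center = (
        float(top.get("beam_center_x_mm", 0.0)),
        float(top.get("beam_center_y_mm", 0.0)),
    )
    panels = []
    gains = []
    for m in sorted(panel_kv):
        kv = panel_kv[m]
        fast_extent = int(kv["max_fs"]) - int(kv["min_fs"]) + 1
        slow_extent = int(kv["max_ss"]) - int(kv["min_ss"]) + 1
        fs = _AXIS_RE.match(kv["fs"])
        ss = _AXIS_RE.match(kv["ss"])
        if fs is None or ss is None:
            raise GeometryError(f"cannot parse axis strings for panel {m}")
        origin = (
            float(kv["corner_x"]) * pixel_size + beam_center[0],
            float(kv["corner_y"]) * pixel_size + beam_center[1],
        )
        panels.append(
            ModulePanel(
                index=m,
                fast_extent=fast_extent,
                slow_extent=slow_extent,
                origin_lab=origin,
                fast_axis=(float(fs.group(1)), float(fs.group(2))),
                slow_axis=(float(ss.group(1)), float(ss.group(2))),
                pixel_size=pixel_size,
            )
        )
        gains.append(float(kv.get("gain", DEFAULT_GAIN_E_PER_ADU)))
    return DetectorGeometry(
        panels=tuple(panels),
        camera_length_mm=camera_length_mm,
        beam_center_mm=beam_center,
        gains=tuple(gains),
    )


# --------------------------------------------------------------------------
# dict / YAML serialization
# --------------------------------------------------------------------------

def geometry_to_dict(geometry: DetectorGeometry) -> dict:
    return {
        "camera_length_mm": geometry.camera_length_mm,
        "beam_center_mm": list(geometry.beam_center_mm),
        "gains": list(geometry.gains),
        "panels": [
            {
                "index": p.index,
                "fast_extent": p.fast_extent,
                "slow_extent": p.slow_extent,
                "origin_lab": list(p.origin_lab),
                "fast_axis": list(p.fast_axis),
                "slow_axis": list(p.slow_axis),
                "pixel_size": p.pixel_size,
            }
            for p in geometry.panels
        ],
    }


def geometry_from_dict(d: dict) -> DetectorGeometry:
    panels = tuple(
        ModulePanel(
            index=pd["index"],
            fast_extent=pd["fast_extent"],
            slow_extent=pd["slow_extent"],
            origin_lab=tuple(pd["origin_lab"]),
            fast_axis=tuple(pd["fast_axis"]),
            slow_axis=tuple(pd["slow_axis"]),
            pixel_size=pd["pixel_size"],
        )
        for pd in d["panels"]
    )
    return DetectorGeometry(
        panels=panels,
        camera_length_mm=d["camera_length_mm"],
        beam_center_mm=tuple(d["beam_center_mm"]),
        gains=tuple(d["gains"]),
    )
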