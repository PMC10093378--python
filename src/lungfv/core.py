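"""Core imaging containers: grids, scalar volumes, binary masks.

All quantitative work in this package happens on a regular 3D voxel grid.
``ImageGrid`` carries the geometry (shape, spacing, origin, anatomical axis
orientation), ``ScalarVolume`` a scalar field on a grid (CT in Hounsfield
units, or perfusion activity in arbitrary concentration units), and
``BinaryMask`` a boolean field (the anatomical lung volume and every
segmentation output).

Only axis-aligned orientations are supported: each voxel axis maps to one
anatomical axis (R/L, A/P, S/I) with a sign. That covers every NIfTI volume
this package writes and the overwhelming majority it would read; oblique
affines are rejected at ingest with an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple, Union

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "BinaryMask",
    "assert_same_grid",
    "GridMismatchError",
    "LungFVError",
]

#: tolerance (mm) under which two grids' spacings/origins count as equal
GRID_TOL_MM = 0.01

_AXIS_CODES = {
    "R": (0, 1.0),
    "L": (0, -1.0),
    "A": (1, 1.0),
    "P": (1, -1.0),
    "S": (2, 1.0),
    "I": (2, -1.0),
}


class LungFVError(Exception):
    """Base class for data/validation errors raised by this package."""


class GridMismatchError(LungFVError):
    """Two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; every entry >= 1.
    spacing_mm : tuple of float
        Voxel edge lengths in mm; every entry > 0.
    origin_mm : tuple of float
        World (anatomical) coordinate of the center of voxel (0, 0, 0).
    orientation : str
        Three-letter anatomical axis code, e.g. ``"RAS"``: voxel axis *i*
        increases toward the *i*-th letter's anatomical direction.
    """

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 entries >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 entries > 0, got {self.spacing_mm}")
        code = self.orientation.upper()
        if len(code) != 3 or {_AXIS_CODES[c][0] for c in code if c in _AXIS_CODES} != {0, 1, 2}:
            raise ValueError(f"orientation must name all three anatomical axes, got {self.orientation!r}")
        object.__setattr__(self, "orientation", code)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in milliliters (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine."""
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        for i, code in enumerate(self.orientation):
            row, sign = _AXIS_CODES[code]
            aff[row, i] = sign * self.spacing_mm[i]
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_centers_world(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers, one 1D array per world axis
        paired with the voxel axis that maps onto it."""
        aff = self.affine
        coords = []
        for i in range(3):
            idx = np.arange(self.shape[i])
            row = np.nonzero(aff[:3, i])[0][0]
            coords.append(aff[row, i] * idx + aff[row, 3])
        return tuple(coords)

    def physical_extent(self) -> np.ndarray:
        """(3, 2) array of [lo, hi] world coordinates spanned by voxel centers."""
        aff = self.affine
        lo = aff[:3, 3].copy()
        hi = aff[:3, 3].copy()
        for i in range(3):
            end = aff[:3, i] * (self.shape[i] - 1)
            lo += np.minimum(end, 0)
            hi += np.maximum(end, 0)
        # re-sort per world axis (sign handling folded in above)
        return np.stack([np.minimum(lo, hi), np.maximum(lo, hi)], axis=1)

    def matches(self, other: "ImageGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and self.orientation == other.orientation
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin_mm, other.origin_mm))
        )


@dataclass
class ScalarVolume:
    """A 3D scalar field on an :class:`ImageGrid`.

    ``modality`` is either ``"CT-HU"`` (Hounsfield units) or ``"activity"``
    (nonnegative activity-concentration values after ingest cleanup).
    ``n_clamped`` records how many negative activity voxels were clamped to
    zero when the volume was read or generated.
    """

    grid: ImageGrid
    values: np.ndarray
    modality: str = "activity"
    n_clamped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if self.modality not in ("CT-HU", "activity"):
            raise ValueError(f"modality must be 'CT-HU' or 'activity', got {self.modality!r}")

    def scaled(self, c: float) -> "ScalarVolume":
        """Return a copy with all values multiplied by ``c`` (> 0)."""
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        return ScalarVolume(self.grid, self.values * c, self.modality)


@dataclass
class BinaryMask:
    """A 3D boolean field on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return bool(np.all(~self.values | other.values))

    def same_voxels(self, other: "BinaryMask") -> bool:
        return bool(np.array_equal(self.values, other.values))

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.grid, self.values & other.values)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(self.grid, ~self.values)


GridCarrier = Union[ScalarVolume, BinaryMask]


def assert_same_grid(a: GridCarrier, b: GridCarrier, tol_mm: float = GRID_TOL_MM) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a grid.

    Shapes and orientation must be identical; spacing and origin must agree
    within ``tol_mm`` (default 0.01 mm) per component. The error message names
    the first differing field.
    """
    ga, gb = a.grid, b.grid
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if ga.orientation != gb.orientation:
        raise GridMismatchError(f"orientation mismatch: {ga.orientation} vs {gb.orientation}")
    for name, va, vb in (("spacing_mm", ga.spacing_mm, gb.spacing_mm),
                         ("origin_mm", ga.origin_mm, gb.origin_mm)):
        for ax, (x, y) in enumerate(zip(va, vb)):
            if abs(x - y) > tol_mm:
                raise GridMismatchError(
                    f"{name} mismatch on axis {ax}: {x} vs {y} (tol {tol_mm} mm)"
                )
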