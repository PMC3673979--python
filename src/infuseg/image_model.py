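"""In-memory volume, bounding-box and mask containers plus intensity normalization.

Voxel indices are 0-based and bounding boxes are half-open ``[lo, hi)`` so
that the number of enclosed voxels is exactly ``prod(hi - lo)``. Spacing is
carried in millimetres per voxel along each array axis; one cubic millimetre
is one microlitre, which keeps volume reporting unit-trivial downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "VoxelGrid",
    "BoundingBox",
    "BinaryMask",
    "DegenerateRangeError",
    "normalize_intensities",
    "extract_box",
    "scatter_box",
]


class DegenerateRangeError(ValueError):
    """Raised when a constant-valued volume cannot be min-max normalized."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar intensity volume with per-axis voxel spacing in mm.

    Parameters
    ----------
    data
        3D array of scalar intensities in arbitrary scanner units.
    spacing
        ``(dx, dy, dz)`` millimetres per voxel along each array axis;
        all components must be strictly positive and finite.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite voxels (NaN/Inf)")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be three positive finite mm values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel-index box, inclusive ``lo`` and exclusive ``hi``."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("lo and hi must be 3-tuples of voxel indices")
        if any(l < 0 for l in lo) or any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"invalid box: lo={lo}, hi={hi} (need 0 <= lo < hi)")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if self.n_voxels < 2:
            raise ValueError("bounding box must enclose at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def check_within(self, shape: Tuple[int, int, int]) -> None:
        if any(h > s for h, s in zip(self.hi, shape)):
            raise IndexError(f"box hi={self.hi} exceeds grid shape {shape}")

    def expand(self, margin: Tuple[int, int, int], shape: Tuple[int, int, int]) -> "BoundingBox":
        """Grow the box by ``margin`` voxels per side, clipped to ``shape``."""
        lo = tuple(max(0, l - m) for l, m in zip(self.lo, margin))
        hi = tuple(min(s, h + m) for h, m, s in zip(self.hi, margin, shape))
        return BoundingBox(lo, hi)


@dataclass(frozen=True)
class BinaryMask:
    """3D boolean mask sharing the geometry of its source grid."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be positive finite mm values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def normalize_intensities(grid: VoxelGrid) -> VoxelGrid:
    """Min-max normalize intensities to [0, 1] over the whole scan.

    The affine map ``x' = (x - min) / (max - min)`` sends the scan minimum
    to 0 and the maximum to 1, preserving the rank order of all voxels.
    Normalizing over the full scan (rather than a sub-region) keeps the
    mapping independent of any operator-drawn bounding box.

    Raises
    ------
    DegenerateRangeError
        If the volume is constant-valued (zero intensity range).
    """
    lo = float(grid.data.min())
    hi = float(grid.data.max())
    if hi <= lo:
        raise DegenerateRangeError(f"constant volume (all values = {lo}): cannot normalize")
    return VoxelGrid((grid.data - lo) / (hi - lo), grid.spacing)


def extract_box(grid: VoxelGrid, box: BoundingBox) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten the boxed sub-volume into a value vector plus an index map.

    Returns
    -------
    values : ndarray, shape (n,)
        Intensities of the boxed voxels, C-order within the box.
    index_map : ndarray, shape (n, 3), int
        Grid coordinates of each value; a bijection onto the box voxels,
        so scattering the values back reconstructs the region exactly.
    """
    box.check_within(grid.shape)
    sub = grid.data[box.slices]
    values = sub.reshape(-1).copy()
    axes = [np.arange(l, h) for l, h in zip(box.lo, box.hi)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    index_map = np.stack([ii.reshape(-1), jj.reshape(-1), kk.reshape(-1)], axis=1)
    return values, index_map


def scatter_box(values: np.ndarray, index_map: np.ndarray, shape: Tuple[int, int, int],
                fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`extract_box`: place values back at their grid coordinates."""
    out = np.full(shape, fill, dtype=np.float64)
    out[index_map[:, 0], index_map[:, 1], index_map[:, 2]] = values
    return out
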