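"""Volume containers and midsagittal-mirror conventions.

All volumes live on a regular grid with isotropic voxel spacing.  The first
array axis is the left-right (x) axis.  The x dimension must be even so that
the mirror plane falls *between* the two central voxel columns and every voxel
has a distinct homotopic partner: voxel ``i`` pairs with voxel ``nx - 1 - i``.

Physical coordinates are centred per axis, i.e. index ``i`` maps to
``(i - (n - 1) / 2) * voxel_size`` so that ``x = 0`` lies on the mirror plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "SeriesVolume",
    "axis_coords",
    "flip_lr",
    "require_even_x",
    "mirror_voxel_index",
]


def require_even_x(shape) -> None:
    """Raise if the x dimension is odd (no distinct mirror partner)."""
    if shape[0] % 2 != 0:
        raise ValueError(
            "x dimension must be even so every voxel has a distinct mirror "
            f"partner across the midsagittal plane; got nx={shape[0]}"
        )


def mirror_voxel_index(i: int, nx: int) -> int:
    """Index of the homotopic partner of x-index ``i`` on a grid of width ``nx``."""
    return nx - 1 - i


def axis_coords(n: int, voxel_size: float) -> np.ndarray:
    """Centred physical coordinates of the ``n`` grid planes along one axis."""
    return (np.arange(n) - (n - 1) / 2.0) * voxel_size


def flip_lr(data: np.ndarray) -> np.ndarray:
    """View of ``data`` mirrored across the midsagittal plane (x reversal)."""
    return data[::-1]


class _Gridded:
    """Shared coordinate helpers for 3D and 4D volumes."""

    data: np.ndarray
    voxel_size: float

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis centred physical coordinates."""
        return tuple(axis_coords(n, self.voxel_size) for n in self.spatial_shape)

    def bounds(self) -> np.ndarray:
        """(3, 2) array of physical (lo, hi) per axis."""
        b = np.empty((3, 2))
        for a, n in enumerate(self.spatial_shape):
            half = (n - 1) / 2.0 * self.voxel_size
            b[a] = (-half, half)
        return b

    def grid_points(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of physical voxel-centre coordinates."""
        cx, cy, cz = self.coords()
        gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical coordinates to fractional voxel indices."""
        points = np.asarray(points, dtype=float)
        shape = np.asarray(self.spatial_shape, dtype=float)
        return points / self.voxel_size + (shape - 1) / 2.0


@dataclass
class VolumeGrid(_Gridded):
    """A 3D scalar intensity volume with a declared midsagittal mirror plane."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class SeriesVolume(_Gridded):
    """A 4D time-series volume: 3D grid x time, with a repetition interval."""

    data: np.ndarray
    voxel_size: float = 1.0
    tr: float = 2.0  # repetition interval, seconds

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"SeriesVolume expects a 4D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]
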