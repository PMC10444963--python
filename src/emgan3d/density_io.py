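"""Density-map container plus read/write, resampling and normalization.

Axis convention
---------------
``DensityMap.data`` is always indexed ``[z, y, x]``.  ``origin`` and
``voxel_size`` are physical ``(x, y, z)`` vectors in Angstrom, so the centre
of voxel ``(iz, iy, ix)`` sits at ``origin + (ix*vx, iy*vy, iz*vz)``.
Files with permuted axis records are canonicalized on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._mrc import MrcFormatError, MrcVolume, read_mrc, write_mrc

__all__ = [
    "DensityMap",
    "DegenerateMapError",
    "read_map",
    "write_map",
    "resample_to_unit_grid",
    "normalize_density",
]


class DegenerateMapError(ValueError):
    """Raised when a map is constant and cannot be min-max normalized."""


@dataclass
class DensityMap:
    """A 3-D scalar density grid with physical placement metadata."""

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        vs = np.asarray(self.voxel_size, dtype=np.float64)
        if vs.ndim == 0:
            vs = np.full(3, float(vs))
        self.voxel_size = vs.reshape(3)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be 3-D with positive dims, got {self.data.shape}")
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.data.copy(), self.origin.copy(), self.voxel_size.copy(), self.label
        )

    def same_frame(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map, canonicalizing axes to (z, y, x) order."""
    try:
        vol = read_mrc(path)
    except MrcFormatError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read map {path!r}: {exc}") from exc
    return DensityMap(vol.data, vol.origin, vol.voxel_size, vol.label)


def write_map(map: DensityMap, path) -> None:
    """Write a map as a standard MRC mode-2 (float32) file."""
    vol = MrcVolume(
        data=map.data, voxel_size=map.voxel_size, origin=map.origin, label=map.label
    )
    try:
        write_mrc(path, vol)
    except OSError as exc:
        raise OSError(f"cannot write map {path!r}: {exc}") from exc


def resample_to_unit_grid(map: DensityMap, target_spacing: float = 1.0) -> DensityMap:
    """Resample onto an isotropic grid by trilinear interpolation.

    The new grid shares the input's origin; points outside the input's
    convex hull evaluate to 0.  Resampling at the input's own (isotropic)
    spacing is the identity.
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    if np.allclose(map.voxel_size, target_spacing, rtol=0, atol=1e-9):
        return map.copy()

    nz, ny, nx = map.shape
    # voxel size is (x, y, z); data axes are (z, y, x)
    old_spacing = map.voxel_size[::-1]
    new_shape = [
        int(np.floor((n - 1) * s / target_spacing)) + 1
        for n, s in zip((nz, ny, nx), old_spacing)
    ]
    grids = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(new_shape, old_spacing)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        map.data.astype(np.float64),
        np.stack([g.ravel() for g in grids]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(new_shape)
    return DensityMap(
        data.astype(np.float32),
        origin=map.origin.copy(),
        voxel_size=np.full(3, float(target_spacing)),
        label=map.label,
    )


def normalize_density(map: DensityMap) -> DensityMap:
    """Clamp negatives to zero, then min-max scale the whole map to [0, 1]."""
    data = np.asarray(map.data, dtype=np.float64)
    data = np.where(data < 0, 0.0, data)
    lo = float(data.min())
    hi = float(data.max())
    if hi - lo <= 0:
        raise DegenerateMapError(
            f"map is constant ({hi}) after clamping; cannot min-max normalize"
        )
    out = (data - lo) / (hi - lo)
    return replace(map.copy(), data=out.astype(np.float32))
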