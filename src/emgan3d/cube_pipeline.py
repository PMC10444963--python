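"""Sliding-cube decomposition and overlap-averaged reconstruction.

Maps are zero-padded upward so a cube of ``cube_size`` voxels translated
with a fixed ``stride`` covers every original voxel; offsets are emitted in
lexicographic (z, y, x) order so batching and merging are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .density_io import DensityMap

__all__ = ["CubeGrid", "CubePair", "extract_cubes", "make_pairs", "merge_cubes"]

DEFAULT_CUBE_SIZE = 25
DEFAULT_STRIDE = 4


@dataclass
class CubeGrid:
    cube_size: int
    stride: int
    offsets: list[tuple[int, int, int]]
    padded_shape: tuple[int, int, int]
    original_shape: tuple[int, int, int]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))


@dataclass
class CubePair:
    exp_cube: np.ndarray
    sim_cube: np.ndarray
    offset: tuple[int, int, int]
    source_map: str = ""

    def __post_init__(self) -> None:
        if self.exp_cube.shape != self.sim_cube.shape:
            raise ValueError(
                f"cube shape mismatch: exp {self.exp_cube.shape} vs sim {self.sim_cube.shape}"
            )


def _axis_offsets(n: int, cube_size: int, stride: int) -> list[int]:
    """Covering offsets 0, stride, ..., up to the smallest multiple of
    stride that is >= n - cube_size."""
    span = max(n - cube_size, 0)
    last = int(np.ceil(span / stride)) * stride
    return list(range(0, last + 1, stride))


def plan_grid(
    shape: tuple[int, int, int],
    cube_size: int = DEFAULT_CUBE_SIZE,
    stride: int = DEFAULT_STRIDE,
    origin=None,
    voxel_size=None,
) -> CubeGrid:
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if cube_size <= 0:
        raise ValueError(f"cube_size must be positive, got {cube_size}")
    if stride > cube_size:
        raise ValueError(f"stride {stride} must not exceed cube_size {cube_size}")
    per_axis = [_axis_offsets(n, cube_size, stride) for n in shape]
    padded = tuple(offs[-1] + cube_size for offs in per_axis)
    offsets = [tuple(o) for o in product(*per_axis)]
    return CubeGrid(
        cube_size=cube_size,
        stride=stride,
        offsets=offsets,
        padded_shape=padded,
        original_shape=tuple(shape),
        origin=np.zeros(3) if origin is None else np.asarray(origin, dtype=np.float64),
        voxel_size=np.ones(3) if voxel_size is None else np.asarray(voxel_size, dtype=np.float64),
    )


def extract_cubes(
    map: DensityMap,
    cube_size: int = DEFAULT_CUBE_SIZE,
    stride: int = DEFAULT_STRIDE,
) -> tuple[CubeGrid, list[np.ndarray]]:
    """Chop a map into overlapping cubes on a regular offset lattice."""
    grid = plan_grid(map.shape, cube_size, stride, map.origin, map.voxel_size)
    pad = [(0, p - n) for p, n in zip(grid.padded_shape, map.shape)]
    padded = np.pad(map.data, pad, mode="constant")
    c = cube_size
    cubes = [padded[oz : oz + c, oy : oy + c, ox : ox + c].copy() for oz, oy, ox in grid.offsets]
    return grid, cubes


def make_pairs(
    exp: DensityMap,
    sim: DensityMap,
    cube_size: int = DEFAULT_CUBE_SIZE,
    stride: int = DEFAULT_STRIDE,
    source_map: str = "",
) -> list[CubePair]:
    """Extract aligned cube pairs, dropping a pair if either cube is all-zero."""
    if not exp.same_frame(sim):
        raise ValueError(
            "experimental and simulated maps are on different frames: "
            f"shapes {exp.shape} vs {sim.shape}, "
            f"origins {exp.origin} vs {sim.origin}, "
            f"voxels {exp.voxel_size} vs {sim.voxel_size}"
        )
    grid, exp_cubes = extract_cubes(exp, cube_size, stride)
    _, sim_cubes = extract_cubes(sim, cube_size, stride)
    pairs = []
    for off, ec, sc in zip(grid.offsets, exp_cubes, sim_cubes):
        if np.any(ec != 0) and np.any(sc != 0):
            pairs.append(CubePair(ec, sc, off, source_map))
    return pairs


def merge_cubes(grid: CubeGrid, cubes: list[np.ndarray]) -> DensityMap:
    """Reassemble cubes into a map, averaging overlapping contributions."""
    if len(cubes) != len(grid.offsets):
        raise ValueError(
            f"got {len(cubes)} cubes for {len(grid.offsets)} grid offsets"
        )
    c = grid.cube_size
    acc = np.zeros(grid.padded_shape, dtype=np.float64)
    cover = np.zeros(grid.padded_shape, dtype=np.int64)
    for (oz, oy, ox), cube in zip(grid.offsets, cubes):
        cube = np.asarray(cube)
        if cube.shape != (c, c, c):
            raise ValueError(f"cube at {(oz, oy, ox)} has shape {cube.shape}, expected {(c, c, c)}")
        acc[oz : oz + c, oy : oy + c, ox : ox + c] += cube
        cover[oz : oz + c, oy : oy + c, ox : ox + c] += 1
    assert cover.min() >= 1
    merged = acc / cover
    oz, oy, ox = grid.original_shape
    return DensityMap(
        merged[:oz, :oy, :ox].astype(np.float32),
        origin=grid.origin.copy(),
        voxel_size=grid.voxel_size.copy(),
    )
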