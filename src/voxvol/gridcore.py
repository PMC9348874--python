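"""Voxel grid over the structure's padded bounding box, and octree tiling.

The grid is axis-aligned and cubic-voxelled; the voxel with index
``(i, j, k)`` has its center at ``origin + ((i, j, k) + 0.5) * g``.  Voxel
membership of any region is decided by this center point (bottom-level
voxels are treated as zero-dimensional points).  The octree view groups
voxels into 2x2x2 blocks per level; dims are always rounded up to a
multiple of ``2**MAX_DEPTH`` so every supported optimization depth tiles
the same grid, which keeps all reported results independent of the depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .chemio import Structure
from .errors import ParameterError, ResourceLimitError

__all__ = ["VoxelType", "CalcParams", "VoxelGrid", "build_grid",
           "octree_blocks", "MAX_DEPTH", "DELTA_DEFAULT"]

#: Largest supported optimization depth; results are invariant across 0..MAX_DEPTH.
MAX_DEPTH = 6

#: Default search-radius correction, in units of voxel side length.
DELTA_DEFAULT = math.sqrt(2.0) / 4.0


class VoxelType(IntEnum):
    """Per-voxel classification labels."""

    UNASSIGNED = 0
    ATOM = 1        # inside an atom's vdW sphere
    CORE_L = 2      # large-probe core (two-probe mode only)
    SHELL_L = 3     # large-probe shell (two-probe mode only)
    CORE_S = 4      # (small-)probe core
    SHELL_S = 5     # (small-)probe shell
    VOID = 6        # probe-excluded void


@dataclass
class CalcParams:
    """Calculation parameters.

    grid_resolution
        Voxel side length g in Å (default 0.2 Å).
    r_probe_small
        Probe radius in Å (the only probe in single-probe mode).
    r_probe_large
        Large probe radius in Å, or None for single-probe mode.
    optimization_depth
        Octree subdivision steps (default 4); does not affect results.
    delta
        Search-radius correction in voxel side lengths (default sqrt(2)/4).
    max_voxels
        Grid memory cap; exceeding it raises ResourceLimitError.
    """

    grid_resolution: float = 0.2
    r_probe_small: float = 1.2
    r_probe_large: float | None = None
    optimization_depth: int = 4
    compute_surfaces: bool = False
    include_hetatm: bool = False
    delta: float = DELTA_DEFAULT
    max_voxels: int = 300_000_000

    def validate(self) -> None:
        if not (self.grid_resolution > 0):
            raise ParameterError("grid resolution must be positive")
        if self.r_probe_small < 0:
            raise ParameterError("probe radius must be non-negative")
        if self.r_probe_large is not None and not (
            self.r_probe_large > self.r_probe_small
        ):
            raise ParameterError(
                "the large probe radius must exceed the small probe radius"
            )
        if not (0 <= self.optimization_depth <= MAX_DEPTH):
            raise ParameterError(
                f"optimization depth must be in 0..{MAX_DEPTH}"
            )
        if self.delta < 0:
            raise ParameterError("delta must be non-negative")

    @property
    def two_probe(self) -> bool:
        return self.r_probe_large is not None

    @property
    def r_probe_outside(self) -> float:
        """The probe that defines the outside envelope (largest probe in use)."""
        return self.r_probe_large if self.two_probe else self.r_probe_small


@dataclass
class VoxelGrid:
    """Axis-aligned cubic voxel grid with per-voxel type and cavity id."""

    origin: np.ndarray            # min corner, Å
    g: float                      # voxel side length, Å
    dims: tuple[int, int, int]
    levels: int                   # octree levels available (= optimization depth)
    types: np.ndarray = field(default=None)       # int8, VoxelType
    cavity_id: np.ndarray = field(default=None)   # int32, 0 = none

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.types is None:
            self.types = np.zeros(self.dims, dtype=np.int8)
        if self.cavity_id is None:
            self.cavity_id = np.zeros(self.dims, dtype=np.int32)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        return self.g ** 3

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis."""
        idx = np.arange(self.dims[axis], dtype=float)
        return self.origin[axis] + (idx + 0.5) * self.g

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.g

    def type_counts(self) -> dict[VoxelType, int]:
        counts = np.bincount(self.types.ravel(), minlength=len(VoxelType))
        return {t: int(counts[t]) for t in VoxelType}


def build_grid(structure: Structure, params: CalcParams) -> VoxelGrid:
    """Lay a voxel grid over the structure's padded bounding box.

    The box covers every atom sphere and is padded by
    ``2*r_probe_outside + 2*g`` per side so the outside probe core forms a
    connected region around the structure.  Dims are rounded up to a
    multiple of ``2**MAX_DEPTH`` (origin stays at the padded min corner;
    the extra voxels extend the max side and simply add outside space).
    """
    params.validate()
    if len(structure.atoms) == 0:
        raise ParameterError("structure contains no atoms")
    g = params.grid_resolution
    pos = structure.positions
    radii = structure.radii
    pad = 2.0 * params.r_probe_outside + 2.0 * g
    lo = (pos - radii[:, None]).min(axis=0) - pad
    hi = (pos + radii[:, None]).max(axis=0) + pad
    tile = 2 ** MAX_DEPTH
    dims = tuple(
        int(-(-math.ceil((hi[a] - lo[a]) / g) // tile) * tile) for a in range(3)
    )
    n = dims[0] * dims[1] * dims[2]
    if n > params.max_voxels:
        raise ResourceLimitError(
            f"grid of {dims} = {n} voxels exceeds the cap of "
            f"{params.max_voxels}; use a coarser grid resolution"
        )
    return VoxelGrid(origin=lo, g=g, dims=dims, levels=params.optimization_depth)


def octree_blocks(grid: VoxelGrid, level: int):
    """Yield the (i0, j0, k0) origins of the disjoint ``2**level``-sided
    blocks tiling the grid, in lexicographic order."""
    if not (0 <= level <= MAX_DEPTH):
        raise ParameterError(f"octree level must be in 0..{MAX_DEPTH}")
    side = 2 ** level
    if any(d % side for d in grid.dims):
        raise ParameterError(f"grid dims {grid.dims} do not tile at level {level}")
    for i in range(0, grid.dims[0], side):
        for j in range(0, grid.dims[1], side):
            for k in range(0, grid.dims[2], side):
                yield (i, j, k)
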