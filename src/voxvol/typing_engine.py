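"""Voxel type assignment in single- and two-probe mode.

Two algorithms do all the work.  The first marks voxels inside an atom
(d < r_atom for some atom) as ATOM, leaves voxels in the buffer band
(r_atom <= d < r_atom + r_probe) unassigned, and marks everything else as
probe core; it runs top-down over octree blocks, classifying a whole block
whenever the conservative distance bounds allow and subdividing otherwise,
with candidate atoms retrieved through the k-d tree.  The second algorithm
resolves the remaining unassigned voxels: a voxel with a probe-core voxel
within the search radius r_search = r_probe/g + delta (voxel units) becomes
probe shell, inheriting the cavity id of its nearest core voxel; otherwise
it becomes probe-excluded void.  The delta term compensates the half-voxel
placement error of discretized boundaries.

Both classification routes (octree and plain per-voxel) use identical
floating-point expressions, which is what makes results bit-identical
across optimization depths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atomsearch import AtomTree, atoms_near, build_tree
from .chemio import Structure
from .errors import ParameterError
from .gridcore import (DELTA_DEFAULT, CalcParams, VoxelGrid, VoxelType,
                       build_grid, octree_blocks)
from . import cavity as _cavity

log = logging.getLogger(__name__)

__all__ = ["NeighborTable", "neighbor_table", "assign_atom_and_core",
           "assign_shell_and_void", "run_single_probe", "run_two_probe"]

_SQRT3_2 = math.sqrt(3.0) / 2.0
_EPS = 1e-9          # safety margin on block half-diagonals: only ever
                     # causes extra subdivision, never a wrong bulk label
_LEAF_SIDE = 4       # blocks at/below this side are evaluated voxel-by-voxel


# ---------------------------------------------------------------------------
# Neighbor table
# ---------------------------------------------------------------------------

@dataclass
class NeighborTable:
    """Relative voxel offsets within ``r_search``, sorted by distance.

    ``entries`` is an (m, 4) int array of rows (di, dj, dk, d2) with
    squared distance d2 in voxel units, sorted by (d2, di, dj, dk) and
    excluding the origin.  ``r_search`` is in voxel side lengths.
    """

    entries: np.ndarray
    r_search: float


def neighbor_table(r_probe: float, g: float, delta: float = DELTA_DEFAULT) -> NeighborTable:
    """Enumerate integer offsets with squared distance <= r_search**2."""
    if g <= 0:
        raise ParameterError("grid resolution must be positive")
    r_search = r_probe / g + delta
    m = math.ceil(r_search)
    r2max = r_search * r_search
    rng = np.arange(-m, m + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    d2 = di * di + dj * dj + dk * dk
    keep = (d2 <= r2max) & (d2 > 0)
    rows = np.column_stack([di[keep], dj[keep], dk[keep], d2[keep]])
    order = np.lexsort((rows[:, 2], rows[:, 1], rows[:, 0], rows[:, 3]))
    return NeighborTable(entries=rows[order], r_search=r_search)


# ---------------------------------------------------------------------------
# Algorithm 1: atom and probe-core types
# ---------------------------------------------------------------------------

def assign_atom_and_core(
    grid: VoxelGrid,
    tree: AtomTree,
    r_probe: float,
    core_label: VoxelType,
    *,
    skip_atom_test: bool = False,
) -> VoxelGrid:
    """First typing pass; writes only to currently-UNASSIGNED voxels.

    With ``skip_atom_test`` (two-probe loop iii) the inside-atom test is
    skipped: the large-probe pass already fixed every ATOM voxel and the
    r_atom condition is probe independent.
    """
    r2 = tree.radii * tree.radii
    rinf = tree.radii + r_probe
    rinf2 = rinf * rinf
    if grid.levels == 0:
        _assign_plain(grid, tree.positions, r2, rinf, rinf2,
                      core_label, skip_atom_test)
        return grid

    axes = [grid.axis_centers(a) for a in range(3)]
    side = 2 ** grid.levels
    h_top = _SQRT3_2 * grid.g * side + _EPS
    for (i0, j0, k0) in octree_blocks(grid, grid.levels):
        center = grid.origin + (np.array([i0, j0, k0]) + side / 2.0) * grid.g
        cand = np.array(atoms_near(tree, center, r_probe + h_top), dtype=int)
        _classify_block(grid, axes, tree.positions, r2, rinf, rinf2,
                        core_label, skip_atom_test, i0, j0, k0, side, cand)
    return grid


def _classify_block(grid, axes, pos, r2, rinf, rinf2, core_label,
                    skip_atom, i0, j0, k0, side, cand) -> None:
    sl = (slice(i0, i0 + side), slice(j0, j0 + side), slice(k0, k0 + side))
    unassigned = grid.types[sl] == VoxelType.UNASSIGNED
    if not unassigned.any():
        return
    if cand.size == 0:
        grid.types[sl][unassigned] = core_label
        return
    if side <= _LEAF_SIDE:
        _evaluate_leaf(grid, axes, pos, r2, rinf, rinf2, core_label,
                       skip_atom, sl, unassigned, cand)
        return
    center = grid.origin + (np.array([i0, j0, k0]) + side / 2.0) * grid.g
    d = np.sqrt(((pos[cand] - center) ** 2).sum(axis=1))
    h = _SQRT3_2 * grid.g * side + _EPS
    if not skip_atom and np.any(d + h < np.sqrt(r2[cand])):
        grid.types[sl][unassigned] = VoxelType.ATOM
        return
    if np.all(d - h >= rinf[cand]):
        grid.types[sl][unassigned] = core_label
        return
    inside_some_inflated = np.any(d + h < rinf[cand])
    outside_all_atoms = skip_atom or np.all(d - h >= np.sqrt(r2[cand]))
    if inside_some_inflated and outside_all_atoms:
        return  # whole block stays in the buffer band
    kept = cand[d < rinf[cand] + h]
    half = side // 2
    for oi in (0, half):
        for oj in (0, half):
            for ok in (0, half):
                _classify_block(grid, axes, pos, r2, rinf, rinf2, core_label,
                                skip_atom, i0 + oi, j0 + oj, k0 + ok, half, kept)


def _evaluate_leaf(grid, axes, pos, r2, rinf, rinf2, core_label,
                   skip_atom, sl, unassigned, cand) -> None:
    """Exact per-voxel evaluation of a small block (zero-dimensional points)."""
    X = axes[0][sl[0]][:, None, None]
    Y = axes[1][sl[1]][None, :, None]
    Z = axes[2][sl[2]][None, None, :]
    shape = (X.size, Y.size, Z.size)
    atom_mask = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)
    for t in cand:
        d2 = (X - pos[t, 0]) ** 2 + (Y - pos[t, 1]) ** 2 + (Z - pos[t, 2]) ** 2
        blocked |= d2 < rinf2[t]
        if not skip_atom:
            atom_mask |= d2 < r2[t]
    if not skip_atom:
        grid.types[sl][unassigned & atom_mask] = VoxelType.ATOM
    grid.types[sl][unassigned & ~blocked] = core_label


def _assign_plain(grid, pos, r2, rinf, rinf2, core_label, skip_atom) -> None:
    """Per-voxel all-atom evaluation (optimization depth 0: no octree).

    Rasterizes each atom's inflated sphere over its local sub-grid; the
    per-voxel comparisons are the same expressions as in the leaf
    evaluation of the octree path.
    """
    axes = [grid.axis_centers(a) for a in range(3)]
    atom_mask = np.zeros(grid.dims, dtype=bool)
    blocked = np.zeros(grid.dims, dtype=bool)
    for t in range(len(pos)):
        box = []
        for a in range(3):
            lo = np.searchsorted(axes[a], pos[t, a] - rinf[t], side="left")
            hi = np.searchsorted(axes[a], pos[t, a] + rinf[t], side="right")
            box.append(slice(lo, hi))
        X = axes[0][box[0]][:, None, None]
        Y = axes[1][box[1]][None, :, None]
        Z = axes[2][box[2]][None, None, :]
        d2 = (X - pos[t, 0]) ** 2 + (Y - pos[t, 1]) ** 2 + (Z - pos[t, 2]) ** 2
        sub = tuple(box)
        blocked[sub] |= d2 < rinf2[t]
        if not skip_atom:
            atom_mask[sub] |= d2 < r2[t]
    unassigned = grid.types == VoxelType.UNASSIGNED
    if not skip_atom:
        grid.types[unassigned & atom_mask] = VoxelType.ATOM
    grid.types[unassigned & ~blocked] = core_label


# ---------------------------------------------------------------------------
# Algorithm 2: probe shell and excluded void
# ---------------------------------------------------------------------------

def assign_shell_and_void(
    grid: VoxelGrid,
    table: NeighborTable,
    core_label: VoxelType,
    shell_label: VoxelType,
    fallback_label: VoxelType,
    *,
    use_reference: bool = False,
) -> VoxelGrid:
    """Second typing pass over the remaining UNASSIGNED voxels.

    A voxel whose nearest core voxel lies within ``table.r_search`` (voxel
    units) becomes ``shell_label`` and inherits that core voxel's cavity
    id; otherwise it becomes ``fallback_label``.  The production path uses
    an exact Euclidean distance transform, which classifies identically to
    scanning the sorted neighbor table (``use_reference=True``, kept for
    cross-checking): both accept exactly the integer offsets with squared
    distance <= r_search**2.
    """
    unassigned = grid.types == VoxelType.UNASSIGNED
    if not unassigned.any():
        return grid
    core = grid.types == core_label
    if not core.any():
        grid.types[unassigned] = fallback_label
        return grid
    if use_reference:
        _shell_reference(grid, table, core, unassigned, shell_label, fallback_label)
        return grid
    dist, idx = ndimage.distance_transform_edt(~core, return_indices=True)
    within = dist * dist <= table.r_search ** 2 * (1.0 + 1e-12)
    shell = unassigned & within
    grid.types[shell] = shell_label
    grid.cavity_id[shell] = grid.cavity_id[idx[0][shell], idx[1][shell], idx[2][shell]]
    grid.types[unassigned & ~within] = fallback_label
    return grid


def _shell_reference(grid, table, core, unassigned, shell_label, fallback_label):
    """Literal neighbor-table scan, one offset at a time in distance order."""
    remaining = unassigned.copy()
    dims = grid.dims
    for di, dj, dk, _d2 in table.entries:
        if not remaining.any():
            break
        src, dst = _shift_slices(dims, (di, dj, dk))
        hit = np.zeros(dims, dtype=bool)
        hit[dst] = core[src]
        hit &= remaining
        if hit.any():
            grid.types[hit] = shell_label
            ids = np.zeros(dims, dtype=grid.cavity_id.dtype)
            ids[dst] = grid.cavity_id[src]
            grid.cavity_id[hit] = ids[hit]
            remaining &= ~hit
    grid.types[remaining] = fallback_label


def _shift_slices(dims, offset):
    """Slices such that dst-indexed voxels see their neighbor at +offset."""
    src, dst = [], []
    for n, o in zip(dims, offset):
        o = int(o)
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

def run_single_probe(structure: Structure, params: CalcParams):
    """Single-probe typing: atom/core pass, cavity flood fill, shell/void pass.

    Returns ``(grid, cavity_records)``; no voxel remains UNASSIGNED.
    """
    params.validate()
    if params.two_probe:
        raise ParameterError("run_single_probe called with a large probe set")
    grid = build_grid(structure, params)
    tree = build_tree(structure.atoms)
    assign_atom_and_core(grid, tree, params.r_probe_small, VoxelType.CORE_S)
    records = _cavity.flood_fill_cores(grid, VoxelType.CORE_S)
    _cavity.label_outside(grid, records, two_probe=False)
    if params.r_probe_small > 0:
        table = neighbor_table(params.r_probe_small, params.grid_resolution,
                               params.delta)
        assign_shell_and_void(grid, table, VoxelType.CORE_S,
                              VoxelType.SHELL_S, VoxelType.VOID)
    else:
        # a zero probe has no shell and no excluded void
        grid.types[grid.types == VoxelType.UNASSIGNED] = VoxelType.CORE_S
    _cavity.update_occupancy(grid, records)
    records = _cavity.sort_cavities(records)
    return grid, records


def run_two_probe(structure: Structure, params: CalcParams):
    """Two-probe typing: the large probe defines the outside envelope, the
    small probe explores the space the large probe cannot occupy.

    Returns ``(grid, cavity_records)`` with cavity types set from entrance
    counts.
    """
    params.validate()
    if not params.two_probe:
        raise ParameterError("run_two_probe requires a large probe radius")
    g = params.grid_resolution
    grid = build_grid(structure, params)
    tree = build_tree(structure.atoms)
    # loop i: atom + large-probe core
    assign_atom_and_core(grid, tree, params.r_probe_large, VoxelType.CORE_L)
    _cavity.demote_enclosed_large_cores(grid)
    # loop ii: large-probe shell; leftovers stay unassigned for the small probe
    table_l = neighbor_table(params.r_probe_large, g, params.delta)
    assign_shell_and_void(grid, table_l, VoxelType.CORE_L,
                          VoxelType.SHELL_L, VoxelType.UNASSIGNED)
    # loop iii: small-probe core within the remaining space
    assign_atom_and_core(grid, tree, params.r_probe_small, VoxelType.CORE_S,
                         skip_atom_test=True)
    records = _cavity.flood_fill_cores(grid, VoxelType.CORE_S)
    _cavity.label_outside(grid, records, two_probe=True)
    # loop iv: small-probe shell and excluded void
    if params.r_probe_small > 0:
        table_s = neighbor_table(params.r_probe_small, g, params.delta)
        assign_shell_and_void(grid, table_s, VoxelType.CORE_S,
                              VoxelType.SHELL_S, VoxelType.VOID)
    else:
        grid.types[grid.types == VoxelType.UNASSIGNED] = VoxelType.CORE_S
    _cavity.update_occupancy(grid, records)
    for rec in records:
        rec.entrances = _cavity.count_entrances(grid, rec)
        rec.cavity_type = ("Isolated" if rec.entrances == 0
                           else "Pocket" if rec.entrances == 1 else "Tunnel")
    records = _cavity.sort_cavities(records)
    return grid, records
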