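"""Cavity segmentation, outside labelling, entrance counting.

Probe-core voxels are segmented into 26-connected components (sharing a
vertex suffices; 6-connectivity would incorrectly split cavities with
sharp features).  The flood fill runs between the two typing passes, so
shell voxels attributed to their nearest core voxel inherit the correct
cavity id and touching cavities are split at the equidistance surface of
their core regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gridcore import VoxelGrid, VoxelType

log = logging.getLogger(__name__)

__all__ = ["CavityRecord", "flood_fill_cores", "label_outside",
           "count_entrances", "sort_cavities", "update_occupancy",
           "demote_enclosed_large_cores"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class CavityRecord:
    """One segmented probe-core region with its attributed shell."""

    id: int
    core_voxels: int
    occ_voxels: int = 0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cavity_type: str = "Isolated"   # Outside / Isolated / Pocket / Tunnel
    entrances: int | None = None    # two-probe mode only
    surf_exc: float | None = None   # probe-excluded surface area, A^2
    surf_acc: float | None = None   # probe-accessible surface area, A^2

    @property
    def is_outside(self) -> bool:
        return self.cavity_type == "Outside"


def flood_fill_cores(grid: VoxelGrid, core_label: VoxelType) -> list[CavityRecord]:
    """Label 26-connected components of ``core_label`` voxels.

    Component ids (1..N) are written into ``grid.cavity_id``; returns one
    record per component with core counts and core-centroid centers.
    """
    core = grid.types == int(core_label)
    labels, n = ndimage.label(core, structure=_CONN26)
    grid.cavity_id[core] = labels[core]
    records = []
    if n:
        counts = np.bincount(labels[core], minlength=n + 1)
        centers = np.array(
            ndimage.center_of_mass(core, labels, index=range(1, n + 1))
        )
        centers = grid.origin + (centers + 0.5) * grid.g
        for cid in range(1, n + 1):
            records.append(CavityRecord(id=cid, core_voxels=int(counts[cid]),
                                        center=centers[cid - 1]))
    return records


def _boundary_ids(mask: np.ndarray, ids: np.ndarray) -> set[int]:
    found: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            sl = tuple(sl)
            found |= set(np.unique(ids[sl][mask[sl]]).tolist())
    found.discard(0)
    return found


def label_outside(grid: VoxelGrid, records: list[CavityRecord],
                  *, two_probe: bool) -> list[CavityRecord]:
    """Mark which core components constitute the outside space.

    Single-probe: every probe-core component containing a grid-boundary
    voxel is 'Outside'; the rest are 'Isolated'.  Two-probe: the outside is
    the boundary-touching large-probe space (already isolated by
    :func:`demote_enclosed_large_cores`); every small-probe component is a
    cavity, typed later from its entrance count.
    """
    if two_probe:
        if not (grid.types == VoxelType.CORE_L).any():
            log.warning("no boundary-reaching large-probe core: grid padding "
                        "too small; all cavities reported Isolated")
        return records
    core = grid.types == VoxelType.CORE_S
    outside = _boundary_ids(core, grid.cavity_id)
    if not outside and records:
        log.warning("no probe-core component reaches the grid boundary: "
                    "grid padding too small; all components reported Isolated")
    for rec in records:
        rec.cavity_type = "Outside" if rec.id in outside else "Isolated"
    return records


def demote_enclosed_large_cores(grid: VoxelGrid) -> None:
    """Return enclosed large-probe core regions to the UNASSIGNED pool.

    Only boundary-touching large-probe core components define the outside
    envelope; an enclosed region big enough for the large probe is still
    interior space and is left for the small probe to claim as a cavity.
    """
    core = grid.types == VoxelType.CORE_L
    if not core.any():
        return
    labels, n = ndimage.label(core, structure=_CONN26)
    keep = _boundary_ids(core, labels)
    if len(keep) < n:
        demote = core & ~np.isin(labels, sorted(keep))
        grid.types[demote] = VoxelType.UNASSIGNED
        log.info("demoted %d enclosed large-probe core voxels", int(demote.sum()))


def update_occupancy(grid: VoxelGrid, records: list[CavityRecord]) -> None:
    """Set occ counts (core + attributed shell) per cavity after pass 2."""
    occ = ((grid.types == VoxelType.CORE_S) | (grid.types == VoxelType.SHELL_S))
    counts = np.bincount(grid.cavity_id[occ],
                         minlength=max((r.id for r in records), default=0) + 1)
    for rec in records:
        rec.occ_voxels = int(counts[rec.id]) if rec.id < len(counts) else 0


def count_entrances(grid: VoxelGrid, record: CavityRecord) -> int:
    """Number of entrances from the outside into one cavity (two-probe).

    The cavity's interface set is its core/shell voxels 6-adjacent to the
    outside space (large-probe core or shell); the entrances are the
    26-connected patches of that set.
    """
    outside = ((grid.types == VoxelType.CORE_L)
               | (grid.types == VoxelType.SHELL_L))
    if not outside.any():
        return 0
    cav = (((grid.types == VoxelType.CORE_S)
            | (grid.types == VoxelType.SHELL_S))
           & (grid.cavity_id == record.id))
    interface = cav & ndimage.binary_dilation(outside, structure=_CONN6)
    if not interface.any():
        return 0
    _, n = ndimage.label(interface, structure=_CONN26)
    return int(n)


def sort_cavities(records: list[CavityRecord]) -> list[CavityRecord]:
    """Descending by occupied volume; ties broken by id."""
    return sorted(records, key=lambda r: (-r.occ_voxels, r.id))
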