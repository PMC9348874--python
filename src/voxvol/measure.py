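"""Volumes, marching-cube surface areas, and unit conversions.

Volumes are voxel tallies times g^3.  Surface areas use a marching-cube
estimator: every 2x2x2 window of voxel centers is reduced to an 8-bit
corner-occupancy pattern; the 256 patterns collapse to 14 classes under
cube rotations, mirrors and inside/outside complement, and each class
carries a per-window area weight (units of g^2).  Naive voxel-face
counting would give a voxelated sphere an area near 6*pi*r^2; the weighted
windows recover 4*pi*r^2.  The default weights are obtained by
least-squares calibration of the 13 free class weights against analytic
sphere areas over a set of voxelized spheres (the all-inside/all-outside
class is pinned to zero) and are frozen below.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .cavity import CavityRecord
from .errors import ParameterError, VoxVolError
from .gridcore import VoxelGrid, VoxelType

log = logging.getLogger(__name__)

__all__ = ["MarchingCubeTable", "default_mc_table", "calibrate_mc_weights",
           "marching_cube_area", "tally_volumes", "compute_surfaces",
           "to_macroscopic", "VolumeReport", "SurfaceReport"]

#: Avogadro-based conversion factors.
_VOL_TO_CM3_PER_G = 0.60221408      # A^3 * (g/mol)^-1 -> cm^3/g
_AREA_TO_M2_PER_G = 6022.1408       # A^2 * (g/mol)^-1 -> m^2/g

_CORNERS = list(itertools.product((0, 1), repeat=3))  # bit = a*4 + b*2 + c


def _build_symmetry_classes() -> tuple[np.ndarray, int]:
    """Map each of the 256 corner patterns to its symmetry class.

    Classes are orbits under the 48 orthogonal cube symmetries plus
    complement; there are 14 of them.  Class ids are assigned in order of
    the smallest pattern in each orbit.
    """
    perms = []
    for axes in itertools.permutations(range(3)):
        for signs in itertools.product((0, 1), repeat=3):
            mapping = np.empty(8, dtype=int)
            for bit, corner in enumerate(_CORNERS):
                moved = tuple(corner[axes[i]] ^ signs[i] for i in range(3))
                mapping[bit] = moved[0] * 4 + moved[1] * 2 + moved[2]
            perms.append(mapping)

    def transform(pattern: int, mapping: np.ndarray) -> int:
        out = 0
        for bit in range(8):
            if pattern >> bit & 1:
                out |= 1 << int(mapping[bit])
        return out

    lookup = np.full(256, -1, dtype=np.int16)
    n_classes = 0
    for start in range(256):
        if lookup[start] >= 0:
            continue
        orbit = {start}
        frontier = [start]
        while frontier:
            p = frontier.pop()
            for mapping in perms:
                for q in (transform(p, mapping), 255 ^ transform(p, mapping)):
                    if q not in orbit:
                        orbit.add(q)
                        frontier.append(q)
        for q in orbit:
            lookup[q] = n_classes
        n_classes += 1
    if lookup.min() < 0:
        raise VoxVolError("marching-cube class lookup does not cover all patterns")
    return lookup, n_classes

_LOOKUP, N_CLASSES = _build_symmetry_classes()
if N_CLASSES != 14:  # pragma: no cover - structural sanity check
    raise VoxVolError(f"expected 14 marching-cube classes, got {N_CLASSES}")

#: Calibrated per-class area weights in units of g^2, indexed by class id
#: (class 0 is the all-inside/all-outside orbit, pinned to zero; classes
#: that never occur on smooth voxelized surfaces keep weight zero).
#: Produced by ``calibrate_mc_weights()`` with its default sphere set.
_DEFAULT_CLASS_WEIGHTS = (
    0.0,
    0.68616170308140956,
    0.6149224987998837,
    0.0,
    0.45347104627242879,
    1.1311166536317963,
    0.0,
    0.21651378796665977,
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
)


@dataclass
class MarchingCubeTable:
    """Per-class area weights plus the 256-entry pattern->class lookup."""

    class_weights: np.ndarray
    lookup: np.ndarray = field(default_factory=lambda: _LOOKUP.copy())

    @property
    def pattern_weights(self) -> np.ndarray:
        return self.class_weights[self.lookup]


def default_mc_table() -> MarchingCubeTable:
    """The calibrated weight table shipped with the package."""
    if _DEFAULT_CLASS_WEIGHTS is None:  # pragma: no cover
        raise VoxVolError("default marching-cube weights missing")
    return MarchingCubeTable(np.asarray(_DEFAULT_CLASS_WEIGHTS, dtype=float))


def _window_patterns(inside: np.ndarray) -> np.ndarray:
    """8-bit corner pattern for every 2x2x2 window of voxel centers."""
    d0, d1, d2 = inside.shape
    ins = inside.astype(np.uint8)
    pat = np.zeros((d0 - 1, d1 - 1, d2 - 1), dtype=np.uint8)
    for bit, (a, b, c) in enumerate(_CORNERS):
        pat |= ins[a:d0 - 1 + a, b:d1 - 1 + b, c:d2 - 1 + c] << np.uint8(bit)
    return pat


def _voxelized_sphere(radius: float, g: float, offset) -> np.ndarray:
    """Boolean inside-mask of one sphere on a centered grid (2-voxel margin)."""
    n = int(np.ceil(2 * radius / g)) + 6
    centers = (np.arange(n) - n / 2 + 0.5) * g
    X = centers[:, None, None] - offset[0]
    Y = centers[None, :, None] - offset[1]
    Z = centers[None, None, :] - offset[2]
    return X * X + Y * Y + Z * Z < radius * radius


def _class_counts(inside: np.ndarray) -> np.ndarray:
    pat = _window_patterns(inside)
    return np.bincount(_LOOKUP[pat].ravel(), minlength=N_CLASSES)


def _sphere_field_counts(ratio: float, n_spheres: int, packing: float, rng):
    """Class counts for a field of disjoint spheres of radius ``ratio``
    voxels at the given packing fraction; returns (counts, analytic area)."""
    from scipy.spatial import cKDTree

    sphere_vol = 4.0 / 3.0 * np.pi * ratio ** 3
    box = (n_spheres * sphere_vol / packing) ** (1.0 / 3.0)
    pos = rng.uniform(0, box, size=(n_spheres, 3))
    for _ in range(300):
        pairs = cKDTree(pos).query_pairs(2 * ratio, output_type="ndarray")
        if pairs.size == 0:
            break
        bad = np.unique(pairs[:, 1])
        pos[bad] = rng.uniform(0, box, size=(bad.size, 3))
    else:
        raise VoxVolError("could not pack calibration sphere field")
    margin = int(np.ceil(ratio)) + 3
    n = int(np.ceil(box)) + 2 * margin
    centers = np.arange(n) + 0.5 - margin
    inside = np.zeros((n, n, n), dtype=bool)
    for p in pos:
        lo = np.maximum(0, np.floor(p - ratio + margin - 1).astype(int))
        hi = np.minimum(n, np.ceil(p + ratio + margin + 1).astype(int))
        X = centers[lo[0]:hi[0]][:, None, None]
        Y = centers[lo[1]:hi[1]][None, :, None]
        Z = centers[lo[2]:hi[2]][None, None, :]
        d2 = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2
        inside[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 < ratio * ratio
    return _class_counts(inside), n_spheres * 4.0 * np.pi * ratio * ratio


def calibrate_mc_weights(
    sphere_ratios=(3.0, 4.0, 6.0, 8.5, 12.0, 17.0, 24.0),
    field_ratios=(0.6, 0.8, 1.0, 1.4, 2.0, 2.5),
    offsets_per_case: int = 8,
    field_spheres: int = 3000,
    packing_fractions=(0.007, 0.015),
    seed: int = 20220623,
    min_class_count: int = 2000,
) -> MarchingCubeTable:
    """Fit the free class weights to analytic sphere areas.

    Voxelization depends only on the radius-to-resolution ratio, so the
    calibration is parametrized by that ratio and spans the range the
    estimator is used over (a sphere of less than ~0.6 voxel radius is not
    reliably representable).  Two kinds of observations enter the
    nonnegative least-squares fit, each row normalized by its analytic
    target so all rows weigh equal relative error:

    * single spheres at well-resolved ratios with random sub-voxel
      offsets, which pin the smooth-surface (low-curvature) limit;
    * fields of many disjoint spheres at coarse ratios, which carry the
      statistics of barely-resolved features, including the window
      configurations produced by nearby features.

    Classes with fewer than ``min_class_count`` observed windows keep
    weight zero (they are too rare to fit stably); the all-inside /
    all-outside class is pinned to zero.  A rank-deficient system over the
    remaining classes raises (add more spheres).
    """
    rng = np.random.default_rng(seed)
    rows, targets = [], []
    for ratio in sphere_ratios:
        for _ in range(offsets_per_case):
            off = rng.uniform(0, 1, size=3)
            rows.append(_class_counts(_voxelized_sphere(ratio, 1.0, off)))
            targets.append(4.0 * np.pi * ratio * ratio)
    for ratio in field_ratios:
        for packing in packing_fractions:
            counts, area = _sphere_field_counts(ratio, field_spheres, packing, rng)
            rows.append(counts)
            targets.append(area)
    A = np.array(rows, dtype=float)
    b = np.array(targets)
    free = np.flatnonzero((A.sum(axis=0) >= min_class_count)
                          & (np.arange(N_CLASSES) != _LOOKUP[0]))
    Aw = A[:, free] / b[:, None]
    if np.linalg.matrix_rank(Aw) < free.size:
        raise VoxVolError(
            "rank-deficient marching-cube calibration; add more sphere "
            "radii/resolutions so every configuration class is observed"
        )
    from scipy.optimize import nnls
    sol, _resid = nnls(Aw, np.ones_like(b))
    weights = np.zeros(N_CLASSES)
    weights[free] = sol
    unseen = set(range(N_CLASSES)) - set(free.tolist()) - {int(_LOOKUP[0])}
    if unseen:
        log.debug("marching-cube classes %s too rare to fit; weight 0",
                  sorted(unseen))
    return MarchingCubeTable(weights)


def _inside_mask(grid: VoxelGrid, inside) -> np.ndarray:
    if isinstance(inside, np.ndarray):
        return inside
    labels = {int(t) for t in inside}
    return np.isin(grid.types, sorted(labels))


def marching_cube_area(grid: VoxelGrid, inside, table: MarchingCubeTable) -> float:
    """Total marching-cube surface area (A^2) of the ``inside`` region.

    ``inside`` is a set of VoxelType labels or a precomputed boolean mask
    over voxel centers; windows are the (dims-1)^3 voxel-center octuplets.
    """
    pat = _window_patterns(_inside_mask(grid, inside))
    w = table.pattern_weights
    return float(w[pat].sum() * grid.g ** 2)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class VolumeReport:
    """All volume quantities in A^3 (macroscopic values via ``macroscopic``)."""

    v_vdw: float
    v_void: float
    v_core: float
    v_shell: float
    v_mol: float
    v_occ: float
    v_mol_isolated: float
    v_acc: float
    total_weight: float
    per_cavity: dict[int, tuple[float, float]] = field(default_factory=dict)
    # cavity id -> (V_core, V_occ)

    def macroscopic(self, quantity: str) -> float:
        """Quantity converted to cm^3/g."""
        return to_macroscopic(getattr(self, quantity), self.total_weight, "volume")


@dataclass
class SurfaceReport:
    """All surface areas in A^2."""

    s_vdw: float
    s_exc: float
    s_acc: float
    s_mol_open: float
    total_weight: float

    def macroscopic(self, quantity: str) -> float:
        """Quantity converted to m^2/g."""
        return to_macroscopic(getattr(self, quantity), self.total_weight, "area")


def tally_volumes(grid: VoxelGrid, records: list[CavityRecord],
                  total_weight: float) -> VolumeReport:
    """Convert voxel tallies into the volume report.

    The combination identities V_mol = V_vdw + V_void and
    V_occ = V_core + V_shell hold exactly by construction.
    """
    counts = grid.type_counts()
    if counts[VoxelType.UNASSIGNED]:
        raise VoxVolError("grid still contains unassigned voxels")
    vv = grid.voxel_volume
    v_vdw = counts[VoxelType.ATOM] * vv
    v_void = counts[VoxelType.VOID] * vv
    v_core = (counts[VoxelType.CORE_S] + counts[VoxelType.CORE_L]) * vv
    v_shell = (counts[VoxelType.SHELL_S] + counts[VoxelType.SHELL_L]) * vv
    v_occ_isolated = sum(r.occ_voxels for r in records
                         if r.cavity_type == "Isolated") * vv
    per_cavity = {r.id: (r.core_voxels * vv, r.occ_voxels * vv) for r in records}
    return VolumeReport(
        v_vdw=v_vdw,
        v_void=v_void,
        v_core=v_core,
        v_shell=v_shell,
        v_mol=v_vdw + v_void,
        v_occ=v_core + v_shell,
        v_mol_isolated=v_vdw + v_void + v_occ_isolated,
        v_acc=v_vdw + v_void + v_shell,
        total_weight=total_weight,
        per_cavity=per_cavity,
    )


def _outside_mask(grid: VoxelGrid, records: list[CavityRecord],
                  two_probe: bool) -> np.ndarray:
    if two_probe:
        return np.isin(grid.types, (int(VoxelType.CORE_L), int(VoxelType.SHELL_L)))
    outside_ids = [r.id for r in records if r.is_outside]
    occ = np.isin(grid.types, (int(VoxelType.CORE_S), int(VoxelType.SHELL_S)))
    return occ & np.isin(grid.cavity_id, outside_ids)


def compute_surfaces(grid: VoxelGrid, records: list[CavityRecord],
                     table: MarchingCubeTable, total_weight: float,
                     two_probe: bool = False) -> SurfaceReport:
    """All global surface areas plus per-cavity S_exc / S_acc.

    S_vdw bounds the atom volume; S_exc additionally encloses the excluded
    void; S_acc additionally encloses all probe shells; S_mol_open is the
    excluded surface facing the outside space only.  Per-cavity areas sum
    the windows containing at least one voxel of that cavity's core+shell;
    windows shared between cavities are split equally.
    """
    inside_vdw = _inside_mask(grid, {VoxelType.ATOM})
    inside_exc = _inside_mask(grid, {VoxelType.ATOM, VoxelType.VOID})
    inside_acc = _inside_mask(
        grid, {VoxelType.ATOM, VoxelType.VOID, VoxelType.SHELL_S, VoxelType.SHELL_L})
    outside = _outside_mask(grid, records, two_probe)

    g2 = grid.g ** 2
    w = table.pattern_weights
    w_exc = w[_window_patterns(inside_exc)]
    w_acc = w[_window_patterns(inside_acc)]

    report = SurfaceReport(
        s_vdw=marching_cube_area(grid, inside_vdw, table),
        s_exc=float(w_exc.sum() * g2),
        s_acc=float(w_acc.sum() * g2),
        s_mol_open=marching_cube_area(grid, ~outside, table),
        total_weight=total_weight,
    )

    # per-cavity attribution with equal split of shared windows
    occ_labels = (int(VoxelType.CORE_S), int(VoxelType.SHELL_S))
    members = []
    for rec in records:
        vox = np.isin(grid.types, occ_labels) & (grid.cavity_id == rec.id)
        d0, d1, d2 = vox.shape
        win = np.zeros((d0 - 1, d1 - 1, d2 - 1), dtype=bool)
        for (a, b, c) in _CORNERS:
            win |= vox[a:d0 - 1 + a, b:d1 - 1 + b, c:d2 - 1 + c]
        members.append(win)
    if members:
        sharing = np.zeros(members[0].shape, dtype=np.int16)
        for win in members:
            sharing += win
        np.maximum(sharing, 1, out=sharing)
        for rec, win in zip(records, members):
            frac = win / sharing
            rec.surf_exc = float((w_exc * frac).sum() * g2)
            rec.surf_acc = float((w_acc * frac).sum() * g2)
    return report


def to_macroscopic(value: float, total_weight: float, kind: str) -> float:
    """Convert a molecular-scale quantity to the macroscopic scale.

    volume: A^3 -> cm^3/g; area: A^2 -> m^2/g, both per mole of structures
    of molar mass ``total_weight``.
    """
    if total_weight <= 0:
        raise ParameterError("total molar mass must be positive")
    if kind == "volume":
        return value * _VOL_TO_CM3_PER_G / total_weight
    if kind == "area":
        return value * _AREA_TO_M2_PER_G / total_weight
    raise ParameterError(f"unknown quantity kind {kind!r}")
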