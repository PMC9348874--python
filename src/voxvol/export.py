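"""Results report and OpenDX surface-map export.

The DX map is a scalar field over the voxel-center lattice encoding the
voxel classification with a monotone code per type, so that a single
isovalue reproduces each surface:

====================  ====  ==========================================
voxel type            code  isovalue giving the enclosing surface
====================  ====  ==========================================
atom                     6  5.5 -> vdW surface
probe-excluded void      5  4.5 -> probe-excluded surface
small-probe shell        4
large-probe shell        3  2.5 -> probe-accessible surface
small-probe core         2
large-probe core         1
====================  ====  ==========================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .cavity import CavityRecord
from .gridcore import VoxelGrid, VoxelType
from .measure import SurfaceReport, VolumeReport

__all__ = ["SurfaceMap", "make_surface_map", "write_dx", "write_report",
           "DX_CODES"]

DX_CODES = {
    VoxelType.UNASSIGNED: 0,
    VoxelType.CORE_L: 1,
    VoxelType.CORE_S: 2,
    VoxelType.SHELL_L: 3,
    VoxelType.SHELL_S: 4,
    VoxelType.VOID: 5,
    VoxelType.ATOM: 6,
}


@dataclass
class SurfaceMap:
    """Scalar field on the voxel-center lattice (axis-aligned deltas)."""

    origin: np.ndarray          # position of grid node (0,0,0), A
    g: float
    counts: tuple[int, int, int]
    values: np.ndarray          # shape == counts

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != tuple(self.counts):
            raise ValueError("surface-map counts and data shape disagree")


def make_surface_map(grid: VoxelGrid, cavity: CavityRecord | None = None) -> SurfaceMap:
    """Encode the typed grid (or one cavity's voxels only) as a SurfaceMap."""
    codes = np.zeros(256, dtype=float)
    for t, c in DX_CODES.items():
        codes[int(t)] = c
    values = codes[grid.types]
    if cavity is not None:
        member = (np.isin(grid.types, (int(VoxelType.CORE_S), int(VoxelType.SHELL_S)))
                  & (grid.cavity_id == cavity.id))
        values = np.where(member, values, 0.0)
    return SurfaceMap(
        origin=grid.origin + 0.5 * grid.g,
        g=grid.g,
        counts=tuple(grid.dims),
        values=values,
    )


def write_dx(surface_map: SurfaceMap, destination) -> None:
    """Write an OpenDX scalar field (gridpositions / gridconnections /
    array), data in z-fastest order, three values per line."""
    nx, ny, nz = surface_map.counts
    ox, oy, oz = surface_map.origin
    g = surface_map.g
    out = io.StringIO()
    out.write("# OpenDX surface map written by voxvol\n")
    out.write("# voxel-type codes: atom=6 void=5 shell_small=4 shell_large=3"
              " core_small=2 core_large=1\n")
    out.write("# data order: x slowest, z fastest\n")
    out.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    out.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
    out.write(f"delta {g:.6f} 0.000000 0.000000\n")
    out.write(f"delta 0.000000 {g:.6f} 0.000000\n")
    out.write(f"delta 0.000000 0.000000 {g:.6f}\n")
    out.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    out.write(f"object 3 class array type double rank 0 items {nx * ny * nz}"
              " data follows\n")
    flat = surface_map.values.reshape(-1)  # C order: z fastest
    for i in range(0, flat.size, 3):
        out.write(" ".join(f"{v:g}" for v in flat[i:i + 3]) + "\n")
    out.write('attribute "dep" string "positions"\n')
    out.write('object "density" class field\n')
    out.write('component "positions" value 1\n')
    out.write('component "connections" value 2\n')
    out.write('component "data" value 3\n')
    text = out.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        try:
            with open(destination, "w") as fh:
                fh.write(text)
        except OSError as e:
            raise OSError(f"cannot write DX map to {destination}: {e}") from e


def write_report(results, destination=None) -> str:
    """Plain-text results report; returns the text, optionally writing it.

    ``results`` is a :class:`voxvol.pipeline.CalcResult`.
    """
    p = results.params
    vol: VolumeReport = results.volumes
    surf: SurfaceReport | None = results.surfaces
    lines: list[str] = []
    add = lines.append
    add("voxvol calculation report")
    add("=" * 60)
    add("Parameters")
    add(f"  grid resolution        {p.grid_resolution:.4f} A")
    if p.two_probe:
        add(f"  small probe radius     {p.r_probe_small:.4f} A")
        add(f"  large probe radius     {p.r_probe_large:.4f} A")
    else:
        add(f"  probe radius           {p.r_probe_small:.4f} A")
    add(f"  optimization depth     {p.optimization_depth}")
    add(f"  grid dims              {'x'.join(str(d) for d in results.grid.dims)}")
    add(f"  atoms                  {len(results.structure.atoms)}")
    add(f"  molar mass             {vol.total_weight:.3f} g/mol")
    add("")
    add("Elements (symbol, radius A, count)")
    seen: dict[str, tuple[float, int]] = {}
    for a in results.structure.atoms:
        r, n = seen.get(a.symbol, (a.radius, 0))
        seen[a.symbol] = (r, n + 1)
    for sym in sorted(seen):
        r, n = seen[sym]
        add(f"  {sym:<2} {r:6.2f}  x{n}")
    add("")
    add("Volumes (A^3, cm^3/g)")
    for label, attr in [("V_vdw", "v_vdw"), ("V_void", "v_void"),
                        ("V_core", "v_core"), ("V_shell", "v_shell"),
                        ("V_mol = V_vdw + V_void", "v_mol"),
                        ("V_occ = V_core + V_shell", "v_occ"),
                        ("V_mol+isolated cavities", "v_mol_isolated"),
                        ("V_acc", "v_acc")]:
        add(f"  {label:<26} {getattr(vol, attr):12.2f}  "
            f"{vol.macroscopic(attr):10.4f}")
    if surf is not None:
        add("")
        add("Surfaces (A^2, m^2/g)")
        for label, attr in [("S_vdw", "s_vdw"), ("S_exc", "s_exc"),
                            ("S_acc", "s_acc"), ("S_mol-open", "s_mol_open")]:
            add(f"  {label:<26} {getattr(surf, attr):12.2f}  "
                f"{surf.macroscopic(attr):10.2f}")
    add("")
    add("Cavities (sorted by decreasing V_occ)")
    cavities = [r for r in results.cavities if not r.is_outside]
    if not cavities:
        add("  none found")
    else:
        header = "  id  type      V_core/A^3   V_occ/A^3"
        if surf is not None:
            header += "   S_exc/A^2   S_acc/A^2"
        header += "   center/A"
        add(header)
        vv = results.grid.voxel_volume
        for r in cavities:
            row = (f"  {r.id:<3} {r.cavity_type:<9}"
                   f" {r.core_voxels * vv:10.2f} {r.occ_voxels * vv:11.2f}")
            if surf is not None:
                row += (f" {r.surf_exc if r.surf_exc is not None else 0.0:11.2f}"
                        f" {r.surf_acc if r.surf_acc is not None else 0.0:11.2f}")
            row += "   ({:.2f}, {:.2f}, {:.2f})".format(*r.center)
            if r.entrances is not None:
                row += f"  entrances={r.entrances}"
            add(row)
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            try:
                with open(destination, "w") as fh:
                    fh.write(text)
            except OSError as e:
                raise OSError(f"cannot write report to {destination}: {e}") from e
    return text
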