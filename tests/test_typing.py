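import math

import numpy as np
import pytest

from voxvol import CalcParams, run_calculation
from voxvol import testkit as tk
from voxvol import typing_engine as te
from voxvol.atomsearch import build_tree
from voxvol.chemio import Atom, Structure
from voxvol.errors import ParameterError
from voxvol.gridcore import VoxelGrid, VoxelType, build_grid
import voxvol.cavity as cavity


class TestNeighborTable:
    def test_inclusion_boundary(self):
        # r_search = 2.0: (1,1,1) has squared distance 3 <= 4; (2,1,0) has 5 > 4
        table = te.neighbor_table(r_probe=2.0, g=1.0, delta=0.0)
        offs = {tuple(row[:3]) for row in table.entries}
        assert (1, 1, 1) in offs
        assert (2, 1, 0) not in offs
        assert (2, 0, 0) in offs  # squared distance exactly 4

    def test_sorted_by_distance_then_offset(self):
        table = te.neighbor_table(r_probe=1.5, g=1.0, delta=0.0)
        d2 = table.entries[:, 3]
        assert np.all(np.diff(d2) >= 0)
        assert tuple(table.entries[0][:3]) == (-1, 0, 0)  # first face neighbor
        assert d2[0] == 1

    def test_zero_probe_table_empty(self):
        table = te.neighbor_table(r_probe=0.0, g=0.2)
        # r_search = sqrt(2)/4 < 1: no integer offset qualifies
        assert len(table.entries) == 0


class TestAtomAndCore:
    def test_distance_rules_single_atom(self, single_h):
        p = CalcParams(grid_resolution=0.2, r_probe_small=1.2)
        grid = build_grid(single_h, p)
        tree = build_tree(single_h.atoms)
        te.assign_atom_and_core(grid, tree, 1.2, VoxelType.CORE_S)
        centers = [grid.axis_centers(a) for a in range(3)]
        d = np.sqrt(centers[0][:, None, None] ** 2
                    + centers[1][None, :, None] ** 2
                    + centers[2][None, None, :] ** 2)
        assert np.all(grid.types[d < 1.2] == VoxelType.ATOM)
        assert np.all(grid.types[(d >= 1.2) & (d < 2.4)] == VoxelType.UNASSIGNED)
        assert np.all(grid.types[d >= 2.4] == VoxelType.CORE_S)

    def test_octree_equals_plain_scan(self, rng):
        """Typing through the octree + k-d tree path is bit-identical to the
        per-voxel all-atom scan on randomized structures."""
        for trial in range(4):
            n = int(rng.integers(2, 12))
            pos = rng.uniform(0, 8, (n, 3))
            radii = rng.uniform(0.7, 1.8, n)
            atoms = [Atom("H", tuple(p), r, 1.0) for p, r in zip(pos, radii)]
            s = Structure(atoms)
            for depth in (2, 4):
                p_oct = CalcParams(grid_resolution=0.35, r_probe_small=1.1,
                                   optimization_depth=depth)
                p_plain = CalcParams(grid_resolution=0.35, r_probe_small=1.1,
                                     optimization_depth=0)
                g1 = build_grid(s, p_oct)
                g0 = build_grid(s, p_plain)
                tree = build_tree(atoms)
                te.assign_atom_and_core(g1, tree, 1.1, VoxelType.CORE_S)
                te.assign_atom_and_core(g0, tree, 1.1, VoxelType.CORE_S)
                assert np.array_equal(g0.types, g1.types)

    def test_typing_matches_independent_classifier(self, rng):
        """Voxel types equal the grid-free point classifier on small grids."""
        n = 6
        pos = rng.uniform(0, 6, (n, 3))
        atoms = [Atom("H", tuple(p), 1.2, 1.0) for p in pos]
        s = Structure(atoms)
        p = CalcParams(grid_resolution=0.5, r_probe_small=1.0)
        grid = build_grid(s, p)
        tree = build_tree(atoms)
        te.assign_atom_and_core(grid, tree, 1.0, VoxelType.CORE_S)
        idx = rng.integers(0, grid.dims[0], size=(300, 3))
        for i in idx:
            c = grid.voxel_center(i)
            label = tk.oracle_point_class(atoms, 1.0, c)
            got = VoxelType(grid.types[tuple(i)])
            want = {"atom": VoxelType.ATOM,
                    "buffer_small": VoxelType.UNASSIGNED,
                    "free": VoxelType.CORE_S}[label]
            assert got == want


class TestShellAndVoid:
    def _grid_with_cores(self, dims, core_voxels):
        grid = VoxelGrid(origin=np.zeros(3), g=1.0, dims=dims, levels=0)
        for i, v in enumerate(core_voxels, start=1):
            grid.types[v] = VoxelType.CORE_S
            grid.cavity_id[v] = i
        return grid

    def test_shell_inherits_nearest_core_id(self):
        grid = self._grid_with_cores((8, 8, 8), [(2, 2, 2)])
        table = te.neighbor_table(1.5, 1.0, delta=0.0)
        te.assign_shell_and_void(grid, table, VoxelType.CORE_S,
                                 VoxelType.SHELL_S, VoxelType.VOID)
        assert grid.types[3, 3, 2] == VoxelType.SHELL_S  # offset (1,1,0), d=sqrt2
        assert grid.cavity_id[3, 3, 2] == 1
        assert grid.types[6, 6, 6] == VoxelType.VOID

    def test_edt_path_equals_reference_scan(self, rng):
        for _ in range(3):
            dims = (16, 16, 16)
            g1 = VoxelGrid(origin=np.zeros(3), g=1.0, dims=dims, levels=0)
            mask = rng.random(dims) < 0.08
            g1.types[mask] = VoxelType.CORE_S
            g1.cavity_id[mask] = 1
            g2 = VoxelGrid(origin=np.zeros(3), g=1.0, dims=dims, levels=0,
                           types=g1.types.copy(), cavity_id=g1.cavity_id.copy())
            table = te.neighbor_table(2.3, 1.0, delta=math.sqrt(2) / 4)
            te.assign_shell_and_void(g1, table, VoxelType.CORE_S,
                                     VoxelType.SHELL_S, VoxelType.VOID)
            te.assign_shell_and_void(g2, table, VoxelType.CORE_S,
                                     VoxelType.SHELL_S, VoxelType.VOID,
                                     use_reference=True)
            assert np.array_equal(g1.types, g2.types)

    def test_single_atoms_rarely_void(self, rng):
        """With delta = sqrt(2)/4 the single-atom excluded void is (at most)
        a handful of boundary-phase voxels; typical runs have none."""
        total_void = 0
        runs = 0
        for _ in range(12):
            r = float(rng.uniform(0.5, 3.0))
            g = float(rng.uniform(0.1, 1.0))
            rp = float(rng.uniform(2 * g, min(6.0, 40 * g)))
            center = tuple(rng.uniform(0, g, 3))
            s = tk.make_fixture(tk.FixtureSpec("single_sphere",
                                               {"radius": r, "center": center}))
            res = run_calculation(s, CalcParams(grid_resolution=g,
                                                r_probe_small=rp))
            nvoid = res.grid.type_counts()[VoxelType.VOID]
            total_void += nvoid
            runs += 1
            assert nvoid <= 60, (r, g, rp, nvoid)
        assert runs == 12
        assert total_void <= 60


class TestRuns:
    def test_single_probe_partition(self, acetylene_run):
        counts = acetylene_run.grid.type_counts()
        assert counts[VoxelType.UNASSIGNED] == 0
        assert counts[VoxelType.ATOM] > 0
        assert counts[VoxelType.CORE_S] > 0

    def test_vdw_volume_of_single_sphere(self, single_h):
        res = run_calculation(single_h, CalcParams(grid_resolution=0.05,
                                                   r_probe_small=1.2))
        expected = 4.0 / 3.0 * math.pi * 1.2 ** 3
        assert res.volumes.v_vdw == pytest.approx(expected, rel=0.005)

    def test_distant_spheres_have_no_void(self):
        s = Structure([Atom("H", (0, 0, 0), 1.2, 1.0),
                       Atom("H", (10, 0, 0), 1.2, 1.0)])
        res = run_calculation(s, CalcParams(grid_resolution=0.25,
                                            r_probe_small=1.2))
        assert res.grid.type_counts()[VoxelType.VOID] == 0
        outside = [r for r in res.cavities if r.is_outside]
        assert len(outside) == 1

    def test_zero_probe_no_shell_no_void(self, single_h):
        res = run_calculation(single_h, CalcParams(grid_resolution=0.2,
                                                   r_probe_small=0.0))
        counts = res.grid.type_counts()
        assert counts[VoxelType.SHELL_S] == 0
        assert counts[VoxelType.VOID] == 0

    def test_core_monotone_in_probe_radius(self, acetylene):
        cores = []
        for rp in (0.8, 1.2, 2.0):
            res = run_calculation(acetylene, CalcParams(grid_resolution=0.25,
                                                        r_probe_small=rp))
            cores.append(res.grid.type_counts()[VoxelType.CORE_S])
        assert cores[0] >= cores[1] >= cores[2]

    def test_two_probe_convex_structure_has_no_inner_core(self, single_h):
        p = CalcParams(grid_resolution=0.25, r_probe_small=1.2,
                       r_probe_large=3.0)
        grid, records = te.run_two_probe(single_h, p)
        assert grid.type_counts()[VoxelType.CORE_S] == 0
        assert records == []

    def test_two_probe_open_cage_has_cavity(self):
        s = tk.make_fixture(tk.FixtureSpec("open_pocket"))
        p = CalcParams(grid_resolution=0.4, r_probe_small=1.2,
                       r_probe_large=3.0)
        grid, records = te.run_two_probe(s, p)
        assert len(records) >= 1
        # the cage center is small-probe core, per the grid-free classifier
        assert tk.oracle_point_class(s.atoms, 1.2, (0, 0, 0)) == "free"
        center_idx = tuple(np.floor((np.zeros(3) - grid.origin) / grid.g).astype(int))
        assert grid.types[center_idx] == VoxelType.CORE_S

    def test_probe_order_validation(self, single_h):
        with pytest.raises(ParameterError):
            CalcParams(r_probe_small=1.2, r_probe_large=0.5).validate()
        with pytest.raises(ParameterError):
            CalcParams(r_probe_small=1.2, r_probe_large=1.2).validate()
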