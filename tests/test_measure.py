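import math

import numpy as np
import pytest

from voxvol import CalcParams, run_calculation
from voxvol import measure
from voxvol import testkit as tk
from voxvol.errors import ParameterError
from voxvol.gridcore import VoxelGrid, VoxelType
from voxvol.measure import (MarchingCubeTable, calibrate_mc_weights,
                            default_mc_table, marching_cube_area,
                            tally_volumes, to_macroscopic)


class TestSymmetryClasses:
    def test_lookup_covers_256_patterns_in_14_classes(self):
        assert measure._LOOKUP.shape == (256,)
        assert set(measure._LOOKUP.tolist()) == set(range(14))

    def test_complement_shares_class(self):
        for p in (0, 1, 3, 23, 105, 200):
            assert measure._LOOKUP[p] == measure._LOOKUP[255 ^ p]

    def test_trivial_classes_weightless(self):
        tab = default_mc_table()
        assert tab.pattern_weights[0] == 0.0
        assert tab.pattern_weights[255] == 0.0


class TestMarchingCubeArea:
    def test_uniform_grid_zero_area(self):
        grid = VoxelGrid(origin=np.zeros(3), g=0.5, dims=(8, 8, 8), levels=0)
        grid.types[:] = VoxelType.ATOM
        assert marching_cube_area(grid, {VoxelType.ATOM},
                                  default_mc_table()) == 0.0

    def test_sphere_area_near_4pi_not_6pi(self):
        """The weighted estimator recovers 4*pi*r^2; naive face counting
        would approach 6*pi*r^2."""
        r, g = 1.2, 0.1
        inside = measure._voxelized_sphere(r, g, np.array([0.031, 0.047, 0.059]))
        area = default_mc_table().pattern_weights[
            measure._window_patterns(inside)].sum() * g * g
        smooth = 4 * math.pi * r * r
        assert area == pytest.approx(smooth, rel=0.01)
        assert abs(area - 6 * math.pi * r * r) / (6 * math.pi * r * r) > 0.25

    def test_matches_skimage_mesh_area(self):
        """Independent cross-check against scikit-image's triangulated
        marching-cubes mesh.  The raw triangle area of a binary volume is
        known to overestimate smooth surfaces by ~5-10%; the calibrated
        window weights remove that bias."""
        from skimage import measure as skmeasure

        r, g = 2.0, 0.1
        inside = measure._voxelized_sphere(r, g, np.array([0.013, 0.021, 0.017]))
        verts, faces, _, _ = skmeasure.marching_cubes(
            inside.astype(float), level=0.5, spacing=(g, g, g))
        mesh_area = skmeasure.mesh_surface_area(verts, faces)
        grid = VoxelGrid(origin=np.zeros(3), g=g, dims=inside.shape, levels=0)
        grid.types[inside] = VoxelType.ATOM
        ours = marching_cube_area(grid, {VoxelType.ATOM}, default_mc_table())
        analytic = 4 * math.pi * r * r
        assert ours == pytest.approx(mesh_area, rel=0.12)  # same surface
        assert ours == pytest.approx(analytic, rel=0.01)
        assert abs(ours - analytic) < abs(mesh_area - analytic)

    def test_acetylene_vdw_error_bound(self, acetylene):
        """At 0.1 A resolution the vdW area is within 0.3% of the analytic
        exposed-cap area."""
        res = run_calculation(acetylene, CalcParams(grid_resolution=0.1,
                                                    r_probe_small=0.0,
                                                    compute_surfaces=True))
        analytic = tk.oracle_union_area(acetylene.atoms, 0.0)
        assert abs(res.surfaces.s_vdw - analytic) / analytic < 0.003


class TestCalibration:
    def test_calibration_agrees_with_frozen_weights(self):
        fitted = calibrate_mc_weights()
        frozen = default_mc_table()
        # both tables estimate a held-out sphere within 0.5% of each other
        inside = measure._voxelized_sphere(2.0, 0.1,
                                           np.array([0.03, 0.05, 0.02]))
        pat = measure._window_patterns(inside)
        a = fitted.pattern_weights[pat].sum()
        b = frozen.pattern_weights[pat].sum()
        assert a == pytest.approx(b, rel=0.005)
        assert a * 0.01 == pytest.approx(4 * math.pi * 4.0, rel=0.01)

    def test_pinned_class_zero_after_fit(self):
        fitted = calibrate_mc_weights()
        assert fitted.class_weights[measure._LOOKUP[0]] == 0.0


class TestVolumes:
    def test_tally_is_count_times_voxel_volume(self):
        grid = VoxelGrid(origin=np.zeros(3), g=0.2, dims=(10, 10, 10), levels=0)
        grid.types[:] = VoxelType.CORE_S
        grid.types.ravel()[:100] = VoxelType.ATOM
        rep = tally_volumes(grid, [], total_weight=1.0)
        assert rep.v_vdw == pytest.approx(100 * 0.008)

    def test_identities_hold_exactly(self, acetylene_run):
        v = acetylene_run.volumes
        assert v.v_mol == v.v_vdw + v.v_void
        assert v.v_occ == v.v_core + v.v_shell
        assert v.v_acc == v.v_vdw + v.v_void + v.v_shell

    def test_sphere_volume_convergence(self, single_h):
        """Voxel volume and marching-cube area converge to the analytic
        sphere values as the resolution is refined."""
        v_true = 4 / 3 * math.pi * 1.2 ** 3
        s_true = 4 * math.pi * 1.2 ** 2
        errs_v, errs_s = [], []
        for g in (1.0, 0.2, 0.05):
            res = run_calculation(single_h, CalcParams(
                grid_resolution=g, r_probe_small=0.0, compute_surfaces=True))
            errs_v.append(abs(res.volumes.v_vdw - v_true) / v_true)
            errs_s.append(abs(res.surfaces.s_vdw - s_true) / s_true)
        assert errs_v[-1] < 0.01 and errs_s[-1] < 0.01
        assert errs_v[-1] <= errs_v[0] and errs_s[-1] <= errs_s[0]

    def test_surface_linear_in_resolution(self):
        """S_vdw(g) follows an approximately linear trend in g at small g
        for a many-atom structure (single small molecules fluctuate more)."""
        s = tk.make_fixture(tk.FixtureSpec(
            "scattered_spheres", {"n": 100, "radius": 1.2, "box": 30.0},
            seed=11))
        gs = np.array([0.5, 0.4, 0.3, 0.2])
        areas = []
        for g in gs:
            res = run_calculation(s, CalcParams(
                grid_resolution=float(g), r_probe_small=0.0,
                compute_surfaces=True))
            areas.append(res.surfaces.s_vdw)
        slope, intercept = np.polyfit(gs, areas, 1)
        residual = np.abs(np.polyval([slope, intercept], gs) - np.array(areas))
        assert residual.max() / np.mean(areas) < 0.005


class TestSurfacesReport:
    def test_single_atom_exc_equals_vdw(self, single_h):
        res = run_calculation(single_h, CalcParams(grid_resolution=0.2,
                                                   r_probe_small=1.2,
                                                   compute_surfaces=True))
        assert res.surfaces.s_exc == res.surfaces.s_vdw  # no void voxels

    def test_accessible_area_is_inflated_sphere(self, single_h):
        res = run_calculation(single_h, CalcParams(grid_resolution=0.1,
                                                   r_probe_small=1.2,
                                                   compute_surfaces=True))
        assert res.surfaces.s_acc == pytest.approx(4 * math.pi * 2.4 ** 2,
                                                   rel=0.01)

    def test_per_cavity_surfaces_assigned(self):
        s = tk.make_fixture(tk.FixtureSpec("fullerene_like"))
        res = run_calculation(s, CalcParams(grid_resolution=0.25,
                                            r_probe_small=1.2,
                                            compute_surfaces=True))
        inner = next(r for r in res.cavities if r.cavity_type == "Isolated")
        assert inner.surf_exc > 0
        assert inner.surf_acc > 0
        assert res.surfaces.s_mol_open <= res.surfaces.s_exc + 1e-9


class TestMacroscopic:
    def test_volume_conversion(self):
        assert to_macroscopic(100.0, 100.0, "volume") == pytest.approx(0.60221408)

    def test_area_conversion(self):
        assert to_macroscopic(100.0, 100.0, "area") == pytest.approx(6022.1408)

    def test_zero_value(self):
        assert to_macroscopic(0.0, 10.0, "volume") == 0.0

    def test_invalid_mass(self):
        with pytest.raises(ParameterError):
            to_macroscopic(1.0, 0.0, "volume")
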