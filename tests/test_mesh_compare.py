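"""Threshold label maps, isosurface meshes and the fidelity metrics."""

import numpy as np
import pytest
import trimesh

import voxelprint as vp
from voxelprint.errors import EmptyMeshError, NonWatertightError
from voxelprint.mesh_compare import OUTSIDE, build_label_map, mesh_metrics


def _unit_cube_mesh():
    """Hand-built 12-triangle unit cube with outward winding."""
    box = trimesh.creation.box(extents=(1, 1, 1))
    return vp.MeshModel(vertices=np.asarray(box.vertices, dtype=float),
                        faces=np.asarray(box.faces, dtype=np.int64))


class TestLabelMap:
    @pytest.fixture()
    def noisy_phantom(self):
        spec = vp.gradient_sphere_spec(shape=(24, 24, 24), spacing=(0.4, 0.4, 0.4),
                                       seed=5)
        return vp.generate_phantom(spec)

    def test_single_division_equals_mask(self, noisy_phantom):
        vol, mask, _ = noisy_phantom
        lo, hi = vp.compute_bounds(vol, mask)
        lm = build_label_map(vol, mask, vp.partition_range(lo, hi, 1))
        np.testing.assert_array_equal(lm.labels == 0, mask.voxels)

    def test_histogram_sums_to_masked_count(self, noisy_phantom):
        vol, mask, _ = noisy_phantom
        lo, hi = vp.compute_bounds(vol, mask)
        lm = build_label_map(vol, mask, vp.partition_range(lo, hi, 10))
        assert lm.histogram().sum() == mask.count()

    def test_matches_bruteforce_threshold_scan(self, noisy_phantom):
        vol, mask, _ = noisy_phantom
        lo, hi = vp.compute_bounds(vol, mask)
        p = vp.partition_range(lo, hi, 6)
        lm = build_label_map(vol, mask, p)
        expect = np.full(vol.shape, OUTSIDE, dtype=int)
        for i in range(6):
            upper = vol.voxels < p.edges[i + 1]
            if i == 5:
                upper |= vol.voxels == p.hi
            sel = mask.voxels & (vol.voxels >= p.edges[i]) & upper
            expect[sel] = i
        np.testing.assert_array_equal(lm.labels, expect)


def _labelmap_from_binary(binary, spacing=(1.0, 1.0, 1.0)):
    vol = vp.ImageVolume(binary.astype(float), spacing=spacing)
    mask = vp.Mask(binary)
    return build_label_map(vol, mask, vp.partition_range(0.5, 1.5, 1))


class TestExtractMesh:
    def test_solid_cube_volume_within_surface_band(self):
        binary = np.zeros((14, 14, 14), bool)
        binary[2:12, 2:12, 2:12] = True  # 10^3 voxels at 1 mm
        m = vp.extract_mesh(_labelmap_from_binary(binary), 0)
        v = vp.mesh_volume(m)
        assert abs(v - 1000.0) <= 300.0  # half-voxel shell of the 600 mm^2 surface
        assert vp.count_components(m) == 1

    def test_single_voxel_closed_component(self):
        binary = np.zeros((5, 5, 5), bool)
        binary[2, 2, 2] = True
        m = vp.extract_mesh(_labelmap_from_binary(binary), 0)
        assert vp.count_components(m) == 1
        assert vp.mesh_volume(m) > 0

    def test_disjoint_blobs_stay_disjoint(self):
        binary = np.zeros((6, 16, 6), bool)
        binary[2:4, 2:5, 2:4] = True
        binary[2:4, 10:13, 2:4] = True
        m = vp.extract_mesh(_labelmap_from_binary(binary), 0)
        assert vp.count_components(m) == 2

    def test_scattered_voxels_one_component_each(self):
        rng = np.random.default_rng(2)
        binary = np.zeros((20, 20, 20), bool)
        # place k isolated voxels on a coarse lattice so none touch
        coords = [(i, j, k) for i in range(2, 19, 4) for j in range(2, 19, 4)
                  for k in range(2, 19, 4)]
        picked = rng.choice(len(coords), size=9, replace=False)
        for idx in picked:
            binary[coords[idx]] = True
        m = vp.extract_mesh(_labelmap_from_binary(binary), 0)
        assert vp.count_components(m) == 9

    def test_empty_division_signalled(self):
        binary = np.ones((4, 4, 4), bool)
        lm = _labelmap_from_binary(binary)
        with pytest.raises(EmptyMeshError):
            vp.extract_mesh(lm, 3)

    def test_smoothing_collapses_thin_regions(self):
        binary = np.zeros((12, 12, 12), bool)
        binary[6, 2:10, 2:10] = True  # one-voxel-thick plate
        lm = _labelmap_from_binary(binary)
        assert vp.mesh_volume(vp.extract_mesh(lm, 0)) > 0
        with pytest.raises(EmptyMeshError):
            vp.extract_mesh(lm, 0, smoothing_sigma_vox=1.0)


class TestMeshVolume:
    def test_unit_cube_exact(self):
        assert vp.mesh_volume(_unit_cube_mesh()) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariant(self):
        m = _unit_cube_mesh()
        shifted = vp.MeshModel(vertices=m.vertices + [103.0, -55.0, 7.0],
                               faces=m.faces)
        assert vp.mesh_volume(shifted) == pytest.approx(vp.mesh_volume(m))

    def test_digitized_sphere_close_to_analytic_and_voxel_count(self):
        spec = vp.PhantomSpec(shape=(50, 50, 50), spacing=(0.5, 0.5, 0.5),
                              layers=[vp.Ellipsoid((12.5, 12.5, 12.5),
                                                   (10, 10, 10), 100.0)])
        vol, mask, _ = vp.generate_phantom(spec)
        lm = build_label_map(vol, mask, vp.partition_range(99, 101, 1))
        v = vp.mesh_volume(vp.extract_mesh(lm, 0))
        analytic = 4 / 3 * np.pi * 10 ** 3
        voxel_count = mask.count() * 0.5 ** 3
        assert v == pytest.approx(analytic, rel=0.02)
        assert v == pytest.approx(voxel_count, rel=0.01)

    def test_open_mesh_reports_hole(self):
        m = _unit_cube_mesh()
        open_mesh = vp.MeshModel(vertices=m.vertices, faces=m.faces[:-1])
        with pytest.raises(NonWatertightError) as exc:
            vp.mesh_volume(open_mesh)
        assert exc.value.boundary_edges == 3


class TestComponents:
    def test_invariant_to_face_and_vertex_permutation(self):
        binary = np.zeros((6, 16, 6), bool)
        binary[2:4, 2:5, 2:4] = True
        binary[2:4, 10:13, 2:4] = True
        m = vp.extract_mesh(_labelmap_from_binary(binary), 0)
        rng = np.random.default_rng(3)
        perm_f = rng.permutation(len(m.faces))
        perm_v = rng.permutation(len(m.vertices))
        inv = np.empty_like(perm_v)
        inv[perm_v] = np.arange(len(perm_v))
        scrambled = vp.MeshModel(vertices=m.vertices[perm_v],
                                 faces=inv[m.faces][perm_f])
        assert vp.count_components(scrambled) == vp.count_components(m) == 2


class TestStl:
    def test_round_trip_preserves_triangles_and_volume(self, tmp_path):
        m = _unit_cube_mesh()
        nbytes = vp.write_stl(m, tmp_path / "cube.stl")
        assert nbytes == (tmp_path / "cube.stl").stat().st_size
        back = trimesh.load(tmp_path / "cube.stl")
        assert len(back.faces) == len(m.faces)
        assert abs(back.volume) == pytest.approx(vp.mesh_volume(m), rel=1e-6)


class TestRunComparison:
    def test_constant_phantom_single_division(self):
        spec = vp.PhantomSpec(shape=(24, 24, 24), spacing=(0.5, 0.5, 0.5),
                              layers=[vp.Ellipsoid((6, 6, 6), (4.5, 4.5, 4.5),
                                                   250.0)])
        vol, mask, _ = vp.generate_phantom(spec)
        rep = vp.run_comparison(vol, mask, division_counts=(3,),
                                make_plots=False)
        nonempty = rep.per_division[rep.per_division.faces > 0]
        assert len(nonempty) == 1  # constant field fills exactly one division
        total = rep.summary.total_mesh_volume_mm3.iloc[0]
        assert total == pytest.approx(rep.reference_volume_mm3, rel=0.05)

    def test_report_artifacts_written(self, tmp_path, small_gradient_sphere):
        vol, mask, _ = small_gradient_sphere
        rep = vp.run_comparison(vol, mask, division_counts=(2, 4),
                                profile=vp.PrinterProfile(dpi_x=150, dpi_y=100,
                                                          layer_mm=0.2),
                                out_dir=tmp_path)
        assert (tmp_path / "report.csv").exists()
        assert (tmp_path / "per_division.csv").exists()
        assert (tmp_path / "audit_panels.png").exists()
        assert any(tmp_path.glob("div_*.stl"))
        assert set(rep.summary.n_divisions) == {2, 4}
        # voxel volume identical across N (it never depends on the LUT)
        assert rep.summary.voxel_volume_mm3.nunique() == 1
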