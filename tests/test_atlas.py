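import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

import afdm
from afdm.errors import ClassificationError, SegmentationError, UndefinedMetricError
from afdm.meshes import RegionLabel


class TestCenterMesh:
    def test_offset_mesh_centered_exactly(self, small_atrium):
        m = small_atrium.copy()
        m.mesh = trimesh.Trimesh(m.vertices + [5.0, 5.0, 5.0], m.faces, process=False)
        out = afdm.center_mesh(m)
        assert np.allclose(out.vertices.mean(axis=0), 0.0, atol=1e-9)

    def test_already_centered_unchanged(self, small_atrium):
        c = afdm.center_mesh(small_atrium)
        c2 = afdm.center_mesh(c)
        assert np.allclose(c.vertices, c2.vertices)

    def test_single_vertex_degenerate(self):
        m = trimesh.Trimesh(np.array([[3.0, 4.0, 5.0]]), np.zeros((0, 3), dtype=int),
                            process=False)
        assert np.allclose(afdm.center_mesh(m).vertices, 0.0)


class TestRegistration:
    def test_identity_registration_is_trivial(self, small_atrium):
        ref = afdm.center_mesh(small_atrium)
        reg = afdm.nonrigid_icp(ref, ref)
        assert reg.rms_post_mm < 1e-6
        assert np.abs(reg.displacement).max() < 1e-3

    def test_rigid_transform_recovered_below_tenth_mm(self, small_atrium):
        ref = afdm.center_mesh(small_atrium)
        r = Rotation.from_euler("xyz", [10, -7, 12], degrees=True).as_matrix()
        src = afdm.center_mesh(
            trimesh.Trimesh(ref.vertices @ r.T + [3.0, -2.0, 1.5], ref.faces, process=False)
        )
        reg = afdm.nonrigid_icp(src, ref)
        assert reg.rms_post_mm < 0.1

    def test_smooth_warp_recovered(self, small_atrium):
        ref = afdm.center_mesh(small_atrium)
        v = ref.vertices
        warp = 4.0 * np.column_stack(
            [np.sin(v[:, 1] / 18.0), np.cos(v[:, 0] / 22.0), np.sin(v[:, 2] / 20.0)]
        )
        src = afdm.center_mesh(trimesh.Trimesh(v + warp, ref.faces, process=False))
        reg = afdm.nonrigid_icp(src, ref)
        assert reg.rms_post_mm <= 0.1 * reg.rms_pre_mm
        assert reg.rms_post_mm <= reg.rms_pre_mm
        # rms decreases monotonically across stiffness stages
        assert all(b <= a + 1e-9 for a, b in zip(reg.stage_rms_mm, reg.stage_rms_mm[1:]))


class TestProjection:
    def test_point_on_vertex_projects_there(self, small_atrium):
        v = small_atrium.vertices[10]
        vals, counts, dropped = afdm.project_scalars([v], [1.0], small_atrium)
        assert vals[10] == 1.0 and counts[10] == 1 and dropped == 0

    def test_two_points_average_on_shared_vertex(self, small_atrium):
        v = small_atrium.vertices[10]
        vals, counts, _ = afdm.project_scalars([v, v + 1e-6], [0.2, 0.4], small_atrium)
        assert vals[10] == pytest.approx(0.3)
        assert counts[10] == 2

    def test_far_point_dropped_and_counted(self, small_atrium):
        far = small_atrium.vertices[0] * 3.0
        vals, _, dropped = afdm.project_scalars([far], [1.0], small_atrium, max_distance_mm=10.0)
        assert dropped == 1 and np.all(np.isnan(vals))

    def test_projection_conserves_mass(self, small_atrium):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, small_atrium.n_vertices, 200)
        pts = small_atrium.vertices[idx] + rng.normal(0, 0.5, (200, 3))
        vals = rng.random(200)
        out, counts, dropped = afdm.project_scalars(pts, vals, small_atrium)
        assert dropped == 0
        obs = counts > 0
        assert np.sum(out[obs] * counts[obs]) == pytest.approx(vals.sum())


class TestSegmentation:
    def test_planted_regions_recovered_from_exact_landmarks(self, atrium):
        labels = afdm.segment_regions(atrium)
        assert (labels == atrium.region).mean() >= 0.99

    def test_planted_regions_recovered_from_imprecise_clicks(self, atrium):
        rng = np.random.default_rng(7)
        nb = atrium.mesh.vertex_neighbors
        jittered = atrium.copy()
        jittered.region_seeds = {
            lab: np.array([rng.choice(nb[v]) for v in vs])
            for lab, vs in atrium.region_seeds.items()
        }
        labels = afdm.segment_regions(jittered)
        assert (labels == atrium.region).mean() >= 0.95

    def test_vertex_5mm_from_ostium_is_antrum(self, atrium):
        d = afdm.geodesic_distance(atrium, np.concatenate(atrium.pv_ostia))
        labels = afdm.segment_regions(atrium)
        near = (d > 0.5) & (d <= 5.0)
        laa_side = afdm.geodesic_distance(atrium, [atrium.laa_apex]) < afdm.geodesic_distance(
            atrium, atrium.pv_ostia[0]
        )
        target = near & ~laa_side
        assert np.all(labels[target] == int(RegionLabel.PV_ANTRA))

    def test_missing_landmark_raises_naming_it(self, atrium):
        broken = atrium.copy()
        broken.laa_apex = None
        with pytest.raises(SegmentationError, match="laa_apex"):
            afdm.segment_regions(broken)
        broken2 = atrium.copy()
        broken2.pv_ostia = []
        with pytest.raises(SegmentationError, match="pv_ostia"):
            afdm.segment_regions(broken2)


class TestDriverLocation:
    def test_pv_ostium_center_inside(self, atrium):
        center = atrium.vertices[atrium.pv_ostia[0]].mean(axis=0)
        assert afdm.classify_driver_location(center, atrium) == "inside"

    def test_laa_apex_outside(self, atrium):
        assert afdm.classify_driver_location(atrium.vertices[atrium.laa_apex], atrium) == "outside"

    def test_site_on_the_line_counts_inside(self, atrium):
        on_line = atrium.vertices[atrium.ablation_line[0][0]]
        assert afdm.classify_driver_location(on_line, atrium) == "inside"

    def test_patient_level_classes(self, atrium):
        inside_pt = atrium.vertices[atrium.pv_ostia[0]].mean(axis=0)
        outside_pt = atrium.vertices[atrium.laa_apex]
        assert afdm.classify_patient_rac_location([], atrium) == "none"
        assert afdm.classify_patient_rac_location([inside_pt], atrium) == "inside_only"
        assert afdm.classify_patient_rac_location([inside_pt, outside_pt], atrium) == "outside"

    def test_missing_line_rejected(self, atrium):
        bare = atrium.copy()
        bare.ablation_line = []
        with pytest.raises(ClassificationError):
            afdm.classify_driver_location(np.zeros(3), bare)

    def test_open_line_rejected(self, atrium):
        leaky = atrium.copy()
        # keep only a fragment of one loop: the PVs leak to the mitral rim
        leaky.ablation_line = [atrium.ablation_line[0][:5]]
        with pytest.raises(ClassificationError, match="open"):
            afdm.classify_driver_location(np.zeros(3), leaky)


class TestVoltageMetrics:
    def test_uniform_map(self, atrium):
        vm = afdm.voltage_metrics(atrium)
        assert vm.mean_mv == pytest.approx(1.0)
        assert all(f == 0.0 for f in vm.area_fraction_below.values())

    def test_half_area_low_voltage_oracle(self, small_atrium):
        at = small_atrium.copy()
        va = at.vertex_areas()
        order = np.argsort(at.vertices[:, 2])
        cum = np.cumsum(va[order])
        k = int(np.searchsorted(cum, va.sum() / 2.0))
        v = np.full(at.n_vertices, 1.0)
        v[order[:k]] = 0.05
        at.voltage_mv = v
        vm = afdm.voltage_metrics(at)
        expected = 100.0 * va[order[:k]].sum() / va.sum()
        for th in (0.5, 0.35, 0.1):
            assert vm.area_fraction_below[th] == pytest.approx(expected, rel=1e-9)

    def test_threshold_fractions_nested(self, small_atrium):
        at = small_atrium.copy()
        rng = np.random.default_rng(1)
        at.voltage_mv = rng.uniform(0.0, 1.2, at.n_vertices)
        vm = afdm.voltage_metrics(at)
        assert vm.area_fraction_below[0.1] <= vm.area_fraction_below[0.35] <= vm.area_fraction_below[0.5]

    def test_unobserved_vertices_excluded(self, small_atrium):
        at = small_atrium.copy()
        v = np.full(at.n_vertices, np.nan)
        v[:10] = 0.2
        at.voltage_mv = v
        vm = afdm.voltage_metrics(at)
        assert vm.mean_mv == pytest.approx(0.2)
        assert vm.area_fraction_below[0.5] == pytest.approx(100.0)

    def test_all_nan_undefined(self, small_atrium):
        at = small_atrium.copy()
        at.voltage_mv = np.full(at.n_vertices, np.nan)
        with pytest.raises(UndefinedMetricError):
            afdm.voltage_metrics(at)
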