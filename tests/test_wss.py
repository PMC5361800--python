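"""Wall shear stress: analytic accuracy, linearity, systolic averaging,
segmental means, velocity MIP."""

import numpy as np
import pytest

from aortaflow import PhantomSpec, make_phantom
from aortaflow.anatomy import (cap_vertices, extract_centerline,
                               extract_surface, orient_centerline,
                               partition_segments, voxel_zones)
from aortaflow.datatypes import LumenMask, VelocityField4D
from aortaflow.wss import (WSSConfig, compute_wss_frame, compute_wss_map,
                           segmental_mean_wss, systolic_average,
                           systolic_window, velocity_mip)


def wall_mean(data, frame=0, cfg=None):
    mesh = extract_surface(data.truth_mask)
    caps = cap_vertices(mesh, data.truth_centerline)
    w, valid = compute_wss_frame(data.velocity, mesh, frame, cfg)
    return np.linalg.norm(w[valid & ~caps], axis=1).mean(), mesh, caps


class TestAnalyticAccuracy:
    def test_poiseuille_within_10_percent(self, poiseuille20):
        mean, _, _ = wall_mean(poiseuille20)
        assert mean == pytest.approx(0.64, rel=0.10)

    def test_error_decreases_with_resolution(self):
        errs = []
        for vpd in (8, 16, 32):
            vox = 20.0 / vpd
            n_xy = int(np.ceil((20 + 6 * vox + 10) / vox))
            spec = PhantomSpec(tube_radius=10.0,
                               grid_shape=(n_xy, n_xy, max(12, int(30 / vox))),
                               voxel_size=vox, n_frames=5, v_max=1.0)
            mean, _, _ = wall_mean(make_phantom(spec))
            errs.append(abs(mean - 0.64) / 0.64)
        assert errs[0] > errs[1] > errs[2]

    def test_tangential_at_every_vertex(self, poiseuille20):
        mesh = extract_surface(poiseuille20.truth_mask)
        w, valid = compute_wss_frame(poiseuille20.velocity, mesh, 0)
        dot = np.abs(np.sum(w[valid] * mesh.normals[valid], axis=1))
        mag = np.linalg.norm(w[valid], axis=1)
        ok = mag > 1e-12
        assert (dot[ok] <= 1e-6 * mag[ok] + 1e-15).all()

    def test_linear_in_velocity_and_viscosity(self, poiseuille20):
        mesh = extract_surface(poiseuille20.truth_mask)
        w1, _ = compute_wss_frame(poiseuille20.velocity, mesh, 0)
        doubled = poiseuille20.velocity.copy()
        doubled.values *= 2.0
        w2, _ = compute_wss_frame(doubled, mesh, 0)
        np.testing.assert_allclose(w2, 2.0 * w1, rtol=1e-6, atol=1e-12)
        w3, _ = compute_wss_frame(poiseuille20.velocity, mesh, 0,
                                  WSSConfig(viscosity=6.4e-3))
        np.testing.assert_allclose(w3, 2.0 * w1, rtol=1e-9, atol=1e-15)

    def test_pulsatile_frames_within_15_percent(self, womersley_pulsatile):
        data = womersley_pulsatile
        mesh = extract_surface(data.truth_mask)
        caps = cap_vertices(mesh, data.truth_centerline)
        for f in range(0, data.spec.n_frames, 2):
            w, valid = compute_wss_frame(data.velocity, mesh, f)
            m = np.linalg.norm(w[valid & ~caps], axis=1).mean()
            assert m == pytest.approx(data.truth_wss[f], rel=0.15)


class TestSystolicAverage:
    def test_time_constant_field(self):
        wf = np.zeros((8, 10, 3))
        wf[..., 0] = 0.5
        np.testing.assert_allclose(systolic_average(wf, 4), 0.5)

    @pytest.mark.parametrize("peak,n,expected", [
        (1, 16, (0, 1, 2, 3, 4)),
        (0, 16, (0, 1, 2, 3, 4)),
        (15, 16, (11, 12, 13, 14, 15)),
        (8, 16, (6, 7, 8, 9, 10)),
    ])
    def test_window_clamped_to_five_frames(self, peak, n, expected):
        assert systolic_window(peak, n) == expected

    def test_too_few_frames_is_error(self):
        with pytest.raises(ValueError):
            systolic_window(0, 4)

    def test_pulsatile_systolic_average_vs_oracle(self, womersley_pulsatile):
        data = womersley_pulsatile
        mesh = extract_surface(data.truth_mask)
        caps = cap_vertices(mesh, data.truth_centerline)
        peak = int(np.argmax(data.truth_waveform))
        wmap = compute_wss_map(data.velocity, mesh, peak)
        window = systolic_window(peak, data.spec.n_frames)
        oracle = data.truth_wss[list(window)].mean()
        est = wmap.wss_sys[wmap.valid & ~caps].mean()
        assert est == pytest.approx(oracle, rel=0.15)


class TestSegmentalMeans:
    def test_uniform_field_gives_uniform_segments(self, ubend):
        mesh = extract_surface(ubend.truth_mask)
        cl = orient_centerline(extract_centerline(ubend.truth_mask),
                               ubend.velocity, ubend.truth_mask, 0)
        part = partition_segments(mesh, cl)
        wss_sys = np.full(mesh.n_vertices, 0.64)
        rep = segmental_mean_wss(wss_sys, part, mesh)
        for lab in range(1, 11):
            assert rep.segment_wss[lab] == pytest.approx(0.64)

    def test_empty_segment_reported_missing(self, ubend):
        mesh = extract_surface(ubend.truth_mask)
        cl = orient_centerline(extract_centerline(ubend.truth_mask),
                               ubend.velocity, ubend.truth_mask, 0)
        part = partition_segments(mesh, cl)
        wss_sys = np.full(mesh.n_vertices, 0.5)
        valid = part.labels != 7
        rep = segmental_mean_wss(wss_sys, part, mesh, valid)
        assert np.isnan(rep.segment_wss[7])
        assert rep.segment_wss[8] == pytest.approx(0.5)

    def test_recirculation_patch_lowers_inner_segment(self):
        spec = PhantomSpec(geometry="u_bend_tube", tube_radius=10.0,
                           bend_radius=50.0, leg_length=20.0,
                           grid_shape=(64, 24, 48), voxel_size=2.5,
                           n_frames=6, v_profile="poiseuille", v_max=1.0,
                           reversed_flow_patch={"arc_fraction": 0.7,
                                                "side": "inner",
                                                "radius": 9.0,
                                                "factor": -0.3},
                           seed=2)
        data = make_phantom(spec)
        mesh = extract_surface(data.truth_mask)
        cl = orient_centerline(extract_centerline(data.truth_mask),
                               data.velocity, data.truth_mask, 0)
        part = partition_segments(mesh, cl)
        caps = cap_vertices(mesh, cl)
        wmap = compute_wss_map(data.velocity, mesh, 0, frames=[0])
        rep = segmental_mean_wss(wmap.wss_sys, part, mesh,
                                 wmap.valid & ~caps)
        assert rep.segment_wss[7] < rep.segment_wss[8]

    def test_invariant_under_mesh_refinement(self, poiseuille_coarse):
        import trimesh

        from aortaflow.datatypes import SurfaceMesh
        data = poiseuille_coarse
        mesh = extract_surface(data.truth_mask)
        cl = orient_centerline(extract_centerline(data.truth_mask),
                               data.velocity, data.truth_mask, 0)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm = tm.subdivide()
        normals = np.array(tm.vertex_normals, dtype=float)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        areas = np.zeros(len(tm.vertices))
        np.add.at(areas, tm.faces.ravel(), np.repeat(tm.area_faces / 3, 3))
        fine = SurfaceMesh(np.asarray(tm.vertices, float),
                           np.asarray(tm.faces), normals, areas)
        means = []
        for m in (mesh, fine):
            part = partition_segments(m, cl)
            caps = cap_vertices(m, cl)
            wmap = compute_wss_map(data.velocity, m, 0, frames=[0])
            rep = segmental_mean_wss(wmap.wss_sys, part, m,
                                     wmap.valid & ~caps)
            means.append([rep.segment_wss[k] for k in range(1, 11)])
        np.testing.assert_allclose(means[0], means[1], rtol=0.05)


class TestVelocityMIP:
    def test_uniform_speed_mip(self):
        vals = np.zeros((5, 10, 10, 10, 3))
        vals[..., 2] = 1.0
        field = VelocityField4D(vals, 1.0, 40.0, (1.5, 1.5, 1.5))
        mask = LumenMask(np.ones((10, 10, 10), bool), 1.0)
        mip, _ = velocity_mip(field, mask, 2, axis=1)
        eroded_footprint = mip > 0
        assert np.allclose(mip[eroded_footprint], 1.0)

    def test_cube_erosion_is_central_core(self):
        vals = np.ones((5, 9, 9, 9, 3))
        field = VelocityField4D(vals, 1.0, 40.0, (2.0, 2.0, 2.0))
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        mip, _ = velocity_mip(field, LumenMask(mask, 1.0), 2, axis=2)
        assert (mip > 0).sum() == 9  # central 3x3 footprint

    def test_erosion_empties_thin_mask_error(self):
        vals = np.ones((5, 8, 8, 8, 3))
        field = VelocityField4D(vals, 1.0, 40.0, (2.0, 2.0, 2.0))
        mask = np.zeros((8, 8, 8), bool)
        mask[4] = True  # one-voxel-thick slab
        with pytest.raises(ValueError, match="erosion"):
            velocity_mip(field, LumenMask(mask, 1.0), 2)

    def test_poiseuille_regional_peak_is_vmax(self, poiseuille20):
        data = poiseuille20
        cl = orient_centerline(extract_centerline(data.truth_mask),
                               data.velocity, data.truth_mask, 0)
        zones = voxel_zones(data.truth_mask, cl)
        _, regional = velocity_mip(data.velocity, data.truth_mask, 2,
                                   axis=1, zones=zones)
        for region in ("AAo", "arch", "DAo"):
            assert regional[region] == pytest.approx(1.0, rel=0.02)

    def test_regional_peak_bounds_segment_speed_means(self, poiseuille20):
        data = poiseuille20
        cl = orient_centerline(extract_centerline(data.truth_mask),
                               data.velocity, data.truth_mask, 0)
        zones = voxel_zones(data.truth_mask, cl)
        _, regional = velocity_mip(data.velocity, data.truth_mask, 2,
                                   axis=1, zones=zones)
        speed = data.velocity.speed(2)
        for region, zz in (("AAo", (1, 2)), ("arch", (3,)), ("DAo", (4, 5))):
            sel = np.isin(zones, zz)
            assert regional[region] >= speed[sel].mean()
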