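"""Anatomy: PC-MRA, lumen segmentation, peak systole, surface, centerline,
ten-segment partition."""

import numpy as np
import pytest

from aortaflow import PhantomSpec, make_phantom
from aortaflow.anatomy import (cap_vertices, compute_pcmra, extract_centerline,
                               extract_surface, find_peak_systole,
                               orient_centerline, partition_segments,
                               segment_lumen, voxel_zones)
from aortaflow.datatypes import LumenMask


def dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestPCMRA:
    def test_static_tissue_is_zero(self, poiseuille20):
        pc = compute_pcmra(poiseuille20.velocity, poiseuille20.magnitude)
        assert np.abs(pc[poiseuille20.tissue_mask]).max() < 5.0  # mag noise only

    def test_constant_speed_formula(self):
        from aortaflow.datatypes import VelocityField4D
        vals = np.zeros((5, 6, 6, 6, 3))
        vals[..., 2] = 1.0
        field = VelocityField4D(vals, 1.0, 40.0, (1.5, 1.5, 1.5))
        pc = compute_pcmra(field, np.full((5, 6, 6, 6), 100.0))
        np.testing.assert_allclose(pc, 100.0)

    def test_radially_decreasing_on_poiseuille(self, poiseuille20):
        pc = compute_pcmra(poiseuille20.velocity, poiseuille20.magnitude)
        nx, ny, nz = poiseuille20.spec.grid_shape
        mid = pc[:, ny // 2, nz // 2]
        center = nx // 2
        # monotone decline from the axis outward (sample along x)
        line = mid[center:center + 9]
        assert np.all(np.diff(line) <= 1e-9)

    def test_frame_mismatch_is_error(self, poiseuille20):
        with pytest.raises(ValueError, match="mismatch"):
            compute_pcmra(poiseuille20.velocity,
                          poiseuille20.magnitude[:-1])


class TestSegmentation:
    def test_noiseless_dice_against_truth(self, poiseuille20):
        pc = compute_pcmra(poiseuille20.velocity, poiseuille20.magnitude)
        mask = segment_lumen(pc, poiseuille20.spec.voxel_size)
        assert dice(mask.mask, poiseuille20.truth_mask.mask) >= 0.95

    def test_largest_component_kept(self):
        pc = np.zeros((30, 20, 20))
        pc[2:6, 5:9, 5:15] = 100.0     # small tube
        pc[10:18, 5:9, 5:15] = 100.0   # twice the volume
        mask = segment_lumen(pc, 1.0, threshold=0.5)
        assert mask.mask[10:18].any() and not mask.mask[2:6].any()

    def test_zero_flow_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            segment_lumen(np.zeros((10, 10, 10)), 1.0, threshold=0.5)

    def test_monotone_in_threshold(self, poiseuille20):
        pc = compute_pcmra(poiseuille20.velocity, poiseuille20.magnitude)
        lo = segment_lumen(pc, 1.0, threshold=0.05)
        hi = segment_lumen(pc, 1.0, threshold=0.3)
        assert not (hi.mask & ~lo.mask).any()  # higher threshold is subset


class TestPeakSystole:
    def test_argmax_of_mean_speed(self):
        from aortaflow.datatypes import VelocityField4D
        vals = np.zeros((5, 4, 4, 4, 3))
        for f, s in enumerate([0.1, 0.6, 0.4, 0.2, 0.1]):
            vals[f, ..., 2] = s
        field = VelocityField4D(vals, 1.0, 40.0, (1.5, 1.5, 1.5))
        mask = LumenMask(np.ones((4, 4, 4), bool), 1.0)
        assert find_peak_systole(field, mask) == 1

    def test_tie_breaks_to_earliest(self):
        from aortaflow.datatypes import VelocityField4D
        vals = np.full((6, 4, 4, 4, 3), 0.3)
        field = VelocityField4D(vals, 1.0, 40.0, (1.5, 1.5, 1.5))
        mask = LumenMask(np.ones((4, 4, 4), bool), 1.0)
        assert find_peak_systole(field, mask) == 0

    def test_matches_programmed_waveform(self, womersley_pulsatile):
        mask = womersley_pulsatile.truth_mask
        peak = find_peak_systole(womersley_pulsatile.velocity, mask)
        assert peak == int(np.argmax(womersley_pulsatile.truth_waveform))

    def test_invariant_under_rescaling(self, womersley_pulsatile):
        field = womersley_pulsatile.velocity.copy()
        field.values *= 3.7
        mask = womersley_pulsatile.truth_mask
        assert find_peak_systole(field, mask) == \
            find_peak_systole(womersley_pulsatile.velocity, mask)


class TestSurface:
    def test_digitized_sphere_area(self):
        n = 26
        x = np.arange(n)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        c = (n - 1) / 2
        mask = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= 100.0
        mesh = extract_surface(LumenMask(mask, 1.0))
        assert mesh.area == pytest.approx(4 * np.pi * 100.0, rel=0.05)

    def test_cube_is_closed_with_euler_2(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        mesh = extract_surface(LumenMask(mask, 1.0))
        v, e, f = len(mesh.vertices), 0, len(mesh.faces)
        edges = set()
        for tri in mesh.faces:
            for i in range(3):
                edges.add(frozenset((tri[i], tri[(i + 1) % 3])))
        assert v - len(edges) + f == 2

    def test_tube_vertices_near_true_cylinder(self, poiseuille20):
        mesh = extract_surface(poiseuille20.truth_mask)
        caps = cap_vertices(mesh, poiseuille20.truth_centerline)
        c = 19.5  # axis position, mm
        r = np.hypot(mesh.vertices[:, 0] - c, mesh.vertices[:, 1] - c)
        err = np.abs(r[~caps] - 10.0)
        assert err.mean() < 0.5  # < half a voxel

    def test_normals_point_outward(self, poiseuille20):
        mesh = extract_surface(poiseuille20.truth_mask)
        caps = cap_vertices(mesh, poiseuille20.truth_centerline)
        c = 19.5
        radial = mesh.vertices[:, :2] - c
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        agree = np.sum(mesh.normals[:, :2] * radial, axis=1)[~caps]
        assert (agree > 0).mean() > 0.99


class TestCenterline:
    def test_straight_tube_on_axis_with_zero_curvature(self, poiseuille20):
        cl = extract_centerline(poiseuille20.truth_mask)
        r = np.hypot(cl.points[:, 0] - 19.5, cl.points[:, 1] - 19.5)
        assert r.max() < 1.0  # within one voxel of the axis
        assert np.linalg.norm(cl.curvature, axis=1).max() < 0.005
        assert cl.length == pytest.approx(35.0, rel=0.05)

    def test_ubend_apex_curvature(self, ubend):
        cl = extract_centerline(ubend.truth_mask)
        frac = cl.arc_fraction()
        kmag = np.linalg.norm(cl.curvature, axis=1)
        apex = kmag[np.argmin(np.abs(frac - 0.5))]
        assert apex == pytest.approx(0.02, rel=0.20)

    def test_ubend_arc_length(self, ubend):
        cl = extract_centerline(ubend.truth_mask)
        geometric = 2 * 20.0 + np.pi * 50.0
        assert cl.length == pytest.approx(geometric, rel=0.05)

    def test_arc_length_strictly_increasing_tangents_unit(self, ubend):
        cl = extract_centerline(ubend.truth_mask)
        assert np.all(np.diff(cl.arc_length) > 0)
        np.testing.assert_allclose(np.linalg.norm(cl.tangents, axis=1), 1.0,
                                   atol=1e-9)

    def test_disconnected_mask_uses_largest_component(self):
        mask = np.zeros((40, 12, 12), bool)
        mask[2:30, 4:9, 4:9] = True
        mask[34:38, 4:9, 4:9] = True
        cl = extract_centerline(LumenMask(mask, 1.0))
        assert cl.length < 32.0  # only the long piece

    def test_orientation_follows_flow(self, poiseuille20):
        cl = extract_centerline(poiseuille20.truth_mask)
        oriented = orient_centerline(cl, poiseuille20.velocity,
                                     poiseuille20.truth_mask, 0)
        # flow is +z: tangents must have positive z on average
        assert oriented.tangents[:, 2].mean() > 0.9
        flipped = orient_centerline(
            Centerline_reversed(oriented), poiseuille20.velocity,
            poiseuille20.truth_mask, 0)
        np.testing.assert_allclose(flipped.tangents, oriented.tangents,
                                   atol=1e-9)


def Centerline_reversed(cl):
    from aortaflow.datatypes import Centerline
    rev = slice(None, None, -1)
    return Centerline(points=cl.points[rev].copy(),
                      arc_length=cl.arc_length[-1] - cl.arc_length[rev],
                      tangents=-cl.tangents[rev],
                      curvature=cl.curvature[rev].copy())


@pytest.fixture(scope="session")
def ubend_partition(ubend):
    mesh = extract_surface(ubend.truth_mask)
    cl = extract_centerline(ubend.truth_mask)
    cl = orient_centerline(cl, ubend.velocity, ubend.truth_mask, 0)
    return mesh, cl, partition_segments(mesh, cl)


class TestPartition:
    def test_labels_disjoint_and_exhaustive(self, ubend_partition):
        mesh, cl, part = ubend_partition
        assert part.labels.shape == (mesh.n_vertices,)
        assert set(np.unique(part.labels)) == set(range(1, 11))

    def test_apex_concave_is_inner_arch(self, ubend_partition):
        mesh, cl, part = ubend_partition
        kmag = np.linalg.norm(cl.curvature, axis=1)
        i = int(np.argmin(np.abs(cl.arc_fraction() - 0.5)))
        kv = cl.curvature[i] / kmag[i]
        inner_pt = cl.points[i] + 10.0 * kv
        outer_pt = cl.points[i] - 10.0 * kv
        vi = np.argmin(np.linalg.norm(mesh.vertices - inner_pt, axis=1))
        vo = np.argmin(np.linalg.norm(mesh.vertices - outer_pt, axis=1))
        assert part.labels[vi] == 5
        assert part.labels[vo] == 6

    def test_default_landmarks_give_five_equal_zones(self, ubend_partition):
        mesh, cl, part = ubend_partition
        zones = (part.labels + 1) // 2
        # zone arc spans: nearest centerline fraction per vertex
        from scipy.spatial import cKDTree
        _, nearest = cKDTree(cl.points).query(mesh.vertices)
        frac = cl.arc_fraction()[nearest]
        for z in range(1, 6):
            sel = zones == z
            assert frac[sel].min() >= (z - 1) * 0.2 - 0.02
            assert frac[sel].max() <= z * 0.2 + 0.02

    def test_mirror_swaps_inner_outer_keeps_zones(self, poiseuille20):
        # straight tube with a fixed reference direction: the vertex
        # mirrored through the axis plane gets the opposite parity label
        mesh = extract_surface(poiseuille20.truth_mask)
        cl = extract_centerline(poiseuille20.truth_mask)
        cl = orient_centerline(cl, poiseuille20.velocity,
                               poiseuille20.truth_mask, 0)
        part = partition_segments(mesh, cl, straight_reference=(1, 0, 0))
        caps = cap_vertices(mesh, cl)
        mirrored = mesh.vertices.copy()
        mirrored[:, 0] = 2 * 19.5 - mirrored[:, 0]
        from scipy.spatial import cKDTree
        tree = cKDTree(mesh.vertices)
        d, j = tree.query(mirrored)
        ok = (~caps) & (d < 0.7) & (~caps[j])
        # off-plane vertices: inner <-> outer, same longitudinal zone
        off_plane = np.abs(mesh.vertices[:, 0] - 19.5) > 2.0
        sel = ok & off_plane
        lab, mlab = part.labels[sel], part.labels[j[sel]]
        # zone boundaries may flip for near-boundary vertices; demand the
        # overwhelming majority
        assert ((lab + 1) // 2 == (mlab + 1) // 2).mean() > 0.98
        assert (((lab % 2) + (mlab % 2)) == 1).mean() > 0.99

    def test_bad_landmarks_rejected(self, ubend_partition):
        mesh, cl, _ = ubend_partition
        with pytest.raises(ValueError, match="landmarks"):
            partition_segments(mesh, cl, landmarks=(0.4, 0.2, 0.6, 0.8))


def test_voxel_zones_cover_lumen_ubend(ubend):
    cl = extract_centerline(ubend.truth_mask)
    cl = orient_centerline(cl, ubend.velocity, ubend.truth_mask, 0)
    zones = voxel_zones(ubend.truth_mask, cl)
    inside = zones[ubend.truth_mask.mask]
    assert inside.min() >= 1 and inside.max() <= 5
    assert (zones[~ubend.truth_mask.mask] == 0).all()
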