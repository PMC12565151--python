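import numpy as np
import pytest
import scipy.sparse as sp
import trimesh

from corofuse.cardiac import lv_volume
from corofuse.synthetic import (
    MotionParams,
    SkinningWeights,
    TubeParams,
    anchors_from_segment_midpoints,
    generate_aortic_root_sequence,
    generate_lv_sequence,
    generate_phase_sequence,
    generate_stenosed_vessel,
    lbs_deform,
    solve_skinning_weights,
)
from corofuse.synthetic import _cotangent_laplacian


def _segments_and_anchors(model, n_seg=2):
    n = len(model.centerline)
    bounds = np.linspace(0, n - 1, n_seg + 1).astype(int)
    segments = [(bounds[i], bounds[i + 1]) for i in range(n_seg)]
    anchors = anchors_from_segment_midpoints(model.mesh, model.centerline, segments)
    return segments, anchors


class TestSkinningWeights:
    def test_single_segment_partition_of_unity(self, static_sequence):
        m = static_sequence[0]
        sw = solve_skinning_weights(m.mesh, [(0, len(m.centerline) - 1)], {0: 0})
        np.testing.assert_array_equal(sw.W, 1.0)

    def test_anchored_vertex_has_unit_weight(self, static_sequence):
        m = static_sequence[0]
        segments, anchors = _segments_and_anchors(m)
        sw = solve_skinning_weights(m.mesh, segments, anchors)
        for vi, j in anchors.items():
            assert sw.W[vi, j] == pytest.approx(1.0, abs=1e-9)

    def test_rows_sum_to_one_and_nonnegative(self, static_sequence):
        m = static_sequence[0]
        segments, anchors = _segments_and_anchors(m, n_seg=3)
        sw = solve_skinning_weights(m.mesh, segments, anchors)
        np.testing.assert_allclose(sw.W.sum(axis=1), 1.0, atol=1e-9)
        assert sw.W.min() >= 0.0

    def test_weights_vary_monotonically_along_tube(self, static_sequence):
        m = static_sequence[0]
        segments, anchors = _segments_and_anchors(m)
        sw = solve_skinning_weights(m.mesh, segments, anchors)
        # ring-averaged weight of segment 0 should decrease from inlet to outlet
        n_theta = 12
        ring_w = sw.W[:, 0].reshape(-1, n_theta).mean(axis=1)
        assert ring_w[0] > 0.9 and ring_w[-1] < 0.1
        diffs = np.diff(ring_w)
        assert (diffs <= 1e-6).all()

    def test_matches_dense_constrained_solve(self, static_sequence):
        # oracle: dense KKT solve of min tr(W^T K W) s.t. anchored rows fixed
        m = static_sequence[0]
        segments, anchors = _segments_and_anchors(m)
        sw = solve_skinning_weights(m.mesh, segments, anchors)
        L, M = _cotangent_laplacian(m.mesh)
        K = (L @ sp.diags(1.0 / M.diagonal()) @ L).toarray()
        n = len(m.mesh.vertices)
        fixed = np.array(sorted(anchors))
        free = np.setdiff1d(np.arange(n), fixed)
        W_dense = np.zeros((n, 2))
        for vi in fixed:
            W_dense[vi, anchors[vi]] = 1.0
        sol = np.linalg.solve(K[np.ix_(free, free)], -K[np.ix_(free, fixed)] @ W_dense[fixed])
        W_dense[free] = sol
        W_dense = np.clip(W_dense, 0, None)
        W_dense /= W_dense.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(sw.W, W_dense, atol=1e-6)

    def test_unanchored_segment_raises_named_error(self, static_sequence):
        m = static_sequence[0]
        segments, anchors = _segments_and_anchors(m)
        anchors_missing = {vi: j for vi, j in anchors.items() if j != 1}
        with pytest.raises(ValueError, match="segment"):
            solve_skinning_weights(m.mesh, segments, anchors_missing)


class TestLBS:
    @staticmethod
    def _weights_and_mesh(seq):
        m = seq[0]
        segments, anchors = _segments_and_anchors(m)
        return m.mesh, solve_skinning_weights(m.mesh, segments, anchors)

    def test_identity_transforms_bitwise(self, static_sequence):
        mesh, sw = self._weights_and_mesh(static_sequence)
        out = lbs_deform(mesh, sw, np.tile(np.eye(4), (2, 1, 1)))
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_common_translation_shifts_all_vertices(self, static_sequence):
        mesh, sw = self._weights_and_mesh(static_sequence)
        T = np.tile(np.eye(4), (2, 1, 1))
        T[:, :3, 3] = [1.0, -2.0, 0.5]
        out = lbs_deform(mesh, sw, T)
        np.testing.assert_allclose(
            out.vertices, mesh.vertices + [1.0, -2.0, 0.5], atol=1e-12
        )

    def test_half_weights_blend_is_average(self):
        # a single vertex with weights (0.5, 0.5) under two opposite rotations
        mesh = trimesh.Trimesh(
            vertices=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            faces=[[0, 1, 2]],
            process=False,
        )
        sw = SkinningWeights(W=np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]]))
        ang = 0.1
        T = np.tile(np.eye(4), (2, 1, 1))
        for k, a in enumerate((ang, -ang)):
            c, s = np.cos(a), np.sin(a)
            T[k, :3, :3] = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        out = lbs_deform(mesh, sw, T)
        v = mesh.vertices[0]
        expected = 0.5 * (T[0, :3, :3] @ v) + 0.5 * (T[1, :3, :3] @ v)
        np.testing.assert_allclose(out.vertices[0], expected, atol=1e-12)

    def test_nonrigid_transform_rejected(self, static_sequence):
        mesh, sw = self._weights_and_mesh(static_sequence)
        T = np.tile(np.eye(4), (2, 1, 1))
        T[0, 0, 0] = 1.1  # scaling, not rotation
        with pytest.raises(ValueError, match="rigid"):
            lbs_deform(mesh, sw, T)

    def test_commutes_with_global_rigid_motion(self, static_sequence):
        # partition of unity => applying one global motion before or after
        # deformation gives the same vertices
        mesh, sw = self._weights_and_mesh(static_sequence)
        ang = 0.3
        c, s = np.cos(ang), np.sin(ang)
        G = np.eye(4)
        G[:3, :3] = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
        G[:3, 3] = [2.0, -1.0, 4.0]
        T = np.tile(G, (2, 1, 1))
        deformed = lbs_deform(mesh, sw, T)
        moved = mesh.vertices @ G[:3, :3].T + G[:3, 3]
        np.testing.assert_allclose(deformed.vertices, moved, atol=1e-9)


class TestPhaseSequence:
    def test_zero_motion_gives_identical_phases(self, small_tube):
        models = generate_phase_sequence(small_tube, MotionParams(0, 0, 0), seed=5)
        assert len(models) == 11
        for m in models[1:]:
            np.testing.assert_array_equal(m.mesh.vertices, models[0].mesh.vertices)

    def test_shared_topology_and_phase_fractions(self, moving_sequence):
        fracs = [m.phase_fraction for m in moving_sequence]
        np.testing.assert_allclose(fracs, np.linspace(0, 1, 11))
        for m in moving_sequence[1:]:
            np.testing.assert_array_equal(m.mesh.faces, moving_sequence[0].mesh.faces)

    def test_periodicity_first_and_last_phase(self, moving_sequence):
        np.testing.assert_allclose(
            moving_sequence[0].mesh.vertices, moving_sequence[-1].mesh.vertices, atol=1e-9
        )

    def test_sectional_volume_conservation(self, small_tube):
        models = generate_phase_sequence(
            small_tube, MotionParams(radial_strain_amplitude=0.05), seed=1
        )
        for m in models:
            eps = m.cross_sections[0].eps_r
            expected = 0.05 * np.sin(2 * np.pi * m.phase_fraction)
            assert eps == pytest.approx(expected, abs=1e-12)
            for cs in m.cross_sections:
                assert np.pi * cs.a * cs.b == pytest.approx(
                    cs.A0 * (1 + cs.eps_r), rel=1e-12
                )

    def test_determinism_same_seed(self, small_tube):
        tube = TubeParams(
            length=small_tube.length, radius=2.0, n_axial=31, n_theta=12, noise_amplitude=0.1
        )
        a = generate_phase_sequence(tube, seed=42)
        b = generate_phase_sequence(tube, seed=42)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.mesh.vertices, mb.mesh.vertices)

    def test_strain_bound_enforced_before_generation(self, small_tube):
        with pytest.raises(ValueError, match="strain"):
            generate_phase_sequence(
                small_tube, MotionParams(radial_strain_amplitude=0.06), seed=0
            )


class TestStenosedVessel:
    def test_zero_severity_is_uniform(self, small_tube):
        models, _ = generate_stenosed_vessel(0.0, small_tube, MotionParams(0, 0, 0), seed=0)
        areas = models[0].centerline.area
        np.testing.assert_allclose(areas, areas[0], rtol=1e-12)

    def test_min_area_matches_severity(self, small_tube):
        models, s_min = generate_stenosed_vessel(0.6, small_tube, MotionParams(0, 0, 0), seed=0)
        areas = models[0].centerline.area
        ref = np.pi * small_tube.radius**2
        assert areas.min() == pytest.approx(0.4 * ref, rel=0.01)
        assert s_min == pytest.approx(0.5 * small_tube.length, rel=0.05)

    def test_same_seed_identical(self, small_tube):
        a, _ = generate_stenosed_vessel(0.5, small_tube, seed=9)
        b, _ = generate_stenosed_vessel(0.5, small_tube, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.mesh.vertices, mb.mesh.vertices)

    def test_severity_out_of_range_rejected(self, small_tube):
        with pytest.raises(ValueError):
            generate_stenosed_vessel(0.96, small_tube)


class TestLVSequence:
    def test_recovers_edv_esv_sv(self):
        meshes = generate_lv_sequence(120.0, 50.0)
        vols = np.array([lv_volume(m) for m in meshes])
        assert vols.max() == pytest.approx(120.0, rel=5e-3)
        assert vols.min() == pytest.approx(50.0, rel=5e-3)
        assert vols.max() - vols.min() == pytest.approx(70.0, rel=5e-3)

    def test_edv_must_exceed_esv(self):
        with pytest.raises(ValueError):
            generate_lv_sequence(50.0, 50.0)

    def test_constant_volume_gives_zero_stroke(self):
        meshes = generate_lv_sequence(100.0, 99.999999)
        vols = np.array([lv_volume(m) for m in meshes])
        assert vols.max() - vols.min() == pytest.approx(0.0, abs=1e-3)


class TestAorticRoot:
    def test_prescribed_regurgitant_volume(self):
        z, A, info = generate_aortic_root_sequence(regurgitant_volume_ml=5.0)
        excess = A[:, info["i_dia"]] - A[:, info["i_avc"]]
        rv = np.trapezoid(excess, z) / 1e3
        assert rv == pytest.approx(5.0, rel=1e-9)

    def test_no_regurgitation_by_default(self):
        z, A, info = generate_aortic_root_sequence()
        np.testing.assert_allclose(A[:, info["i_dia"]], A[:, info["i_avc"]])
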