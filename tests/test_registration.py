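"""Scale matching, ICP variants, global registration and the scale sweep."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facesym import (
    HomogeneousTransform,
    RegistrationConfig,
    apply_scale,
    centroid_init_transform,
    estimate_normals,
    global_registration,
    icp_point_to_plane,
    icp_point_to_point,
    inlier_rmse,
    register,
    scale_factor,
    similarity_transform,
    umeyama_similarity,
)
from facesym.errors import (
    DegenerateGeometryError,
    NoOverlapError,
    ValidationError,
)


class TestScaleFactor:
    def test_identity_pair_gives_one(self, template_478):
        src = template_478[0].points
        assert scale_factor(src, src, 7) == 1.0

    @pytest.mark.parametrize(
        "s,t,expected",
        [
            ((3, 4, 0), (6, 8, 0), 0.5),
            ((1, 1, 1), (2, 0, 0), math.sqrt(3) / 2),
        ],
    )
    def test_closed_form_norm_ratios(self, s, t, expected):
        src = np.array([s], dtype=float)
        tgt = np.array([t], dtype=float)
        assert scale_factor(src, tgt, 0) == pytest.approx(expected, abs=1e-12)

    def test_origin_shift_changes_ratio(self):
        src = np.array([[3.0, 4.0, 0.0]])
        tgt = np.array([[6.0, 8.0, 0.0]])
        assert scale_factor(src, tgt, 0, origin=(6, 8, -5)) == pytest.approx(
            np.linalg.norm([3, 4, 5]) / 5.0, abs=1e-12
        )

    def test_target_at_origin_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            scale_factor(np.array([[1.0, 0, 0]]), np.array([[0.0, 0, 0]]), 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 477))
    def test_reciprocal_under_argument_swap(self, template_478, i):
        src = template_478[0].points
        tgt = src * 1.37 + 0.05  # generic second cloud, no zero norms
        prod = scale_factor(src, tgt, i) * scale_factor(tgt, src, i)
        assert prod == pytest.approx(1.0, abs=1e-12)


class TestApplyScale:
    def test_factor_one_is_identity(self, template_478):
        ls = template_478[0]
        assert np.array_equal(apply_scale(ls, 1.0).points, ls.points)

    def test_scaling_about_origin(self):
        out = apply_scale(np.array([[1.0, 2.0, 3.0]]), 2.0)
        assert np.allclose(out, [[2, 4, 6]])

    def test_matches_ith_norms_after_scale_matching(self, template_478):
        src = template_478[0].points
        tgt = 1.83 * src + np.array([0.01, -0.02, 0.005])
        i = 42
        scaled = apply_scale(tgt, scale_factor(src, tgt, i))
        assert np.linalg.norm(scaled[i]) == pytest.approx(np.linalg.norm(src[i]), abs=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError):
            apply_scale(np.zeros((3, 3)), -1.0)


class TestEstimateNormals:
    def test_planar_grid_normals_are_z(self):
        g = np.linspace(0, 1, 7)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        normals = estimate_normals(pts, k=8)
        assert np.allclose(normals, [0, 0, 1], atol=1e-9)

    def test_sphere_normals_close_to_radial(self, rng):
        # upper hemisphere so the +z orientation rule matches the radial field
        pts = rng.standard_normal((500, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts[:, 2] = np.abs(pts[:, 2])
        normals = estimate_normals(pts, k=12)
        cosang = np.abs(np.einsum("ij,ij->i", normals, pts))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 15.0

    def test_k_must_be_smaller_than_n(self):
        with pytest.raises(ValidationError):
            estimate_normals(np.zeros((10, 3)), k=10)


class TestInlierRmse:
    def test_identity_zero(self, template_478):
        src = template_478[0]
        rmse, res = inlier_rmse(src, src, HomogeneousTransform.identity())
        assert rmse == 0.0 and np.all(res == 0)

    def test_three_four_five_residual(self):
        rmse, res = inlier_rmse(
            np.array([[0.0, 0, 0]]), np.array([[3.0, 4, 0]]), HomogeneousTransform.identity()
        )
        assert rmse == pytest.approx(5.0) and res[0] == pytest.approx(5.0)

    def test_rmse_combines_residuals_per_definition(self):
        src = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        tgt = np.array([[3.0, 0, 0], [0.0, 4, 0]])
        rmse, res = inlier_rmse(src, tgt, HomogeneousTransform.identity())
        assert sorted(res) == [3.0, 4.0]
        assert rmse == pytest.approx(math.sqrt(12.5), abs=1e-12)

    def test_invariant_under_rigid_conjugation(self, template_478, rng):
        src = template_478[0].points
        tgt = src + 0.01 * rng.standard_normal(src.shape)
        T = similarity_transform(1.0, (3, 5, -2), (0.01, 0, 0.02))
        g = similarity_transform(1.0, (30, -40, 25), (0.4, -0.2, 0.9))
        base, _ = inlier_rmse(src, tgt, T)
        conj = g.compose(T).compose(g.inverse())
        moved, _ = inlier_rmse(g.apply(src), g.apply(tgt), conj)
        assert moved == pytest.approx(base, abs=1e-9)


class TestCentroidInit:
    def test_identity_for_equal_sets(self, template_478):
        src = template_478[0]
        assert np.allclose(centroid_init_transform(src, src).matrix, np.eye(4))

    def test_source_minus_target_sign_convention(self):
        src = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        tgt = src + np.array([1.0, 2.0, 3.0])
        T = centroid_init_transform(src, tgt)
        assert np.allclose(T.translation, [-1, -2, -3])

    def test_single_point_translation(self):
        T = centroid_init_transform(np.array([[5.0, 0, 0]]), np.array([[2.0, 0, 0]]))
        assert np.allclose(T.translation, [3, 0, 0])


class TestUmeyama:
    def test_identity(self, template_478):
        src = template_478[0]
        T, rmse = umeyama_similarity(src, src)
        assert rmse == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_exact_recovery_of_known_similarity(self, template_478):
        src = template_478[0].points
        M = similarity_transform(1.37, (12, -25, 8), (0.3, -0.1, 0.2))
        T, rmse = umeyama_similarity(src, M.apply(src))
        assert rmse < 1e-10
        assert np.abs(T.matrix - M.matrix).max() < 1e-10

    def test_noise_floor_matches_sigma(self, template_478):
        src = template_478[0].points
        sigma = 0.01
        rng = np.random.default_rng(0)
        tgt = src + sigma * rng.standard_normal(src.shape)
        _, rmse = umeyama_similarity(src, tgt)
        # per-axis sd sigma on one side -> 3D residual RMS ~ sqrt(3)*sigma
        assert 0.8 * math.sqrt(3) * sigma < rmse < 1.2 * math.sqrt(3) * sigma


class TestGlobalRegistration:
    def test_rotated_translated_cloud_is_coarsely_aligned(self, template_478):
        from scipy.spatial import cKDTree

        src = template_478[0].points
        M = similarity_transform(1.0, (0, 20, 0), (0.05, -0.03, 0.02))
        tgt = M.apply(src)
        T = global_registration(src, tgt, RegistrationConfig(random_seed=0))
        moved = T.apply(src)
        d, _ = cKDTree(tgt).query(moved)
        diag = np.linalg.norm(tgt.max(0) - tgt.min(0))
        assert d.mean() < 0.05 * diag

    def test_identity_clouds_align_to_machine_precision(self, template_478):
        src = template_478[0]
        T = global_registration(src, src)
        rmse, _ = inlier_rmse(src, src, T)
        assert rmse <= 1e-6

    def test_collinear_points_are_degenerate(self):
        pts = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        with pytest.raises(DegenerateGeometryError):
            global_registration(pts, pts)


class TestICP:
    def test_p2plane_ground_truth_init_is_fixed_point(self, template_478):
        src = template_478[0].points
        M = similarity_transform(1.0, (0, 10, 5))
        tgt = M.apply(src)
        normals = estimate_normals(tgt, 12)
        T, rmse = icp_point_to_plane(src, tgt, normals, M)
        assert rmse < 1e-12
        assert np.abs(T.matrix - M.matrix).max() < 1e-10

    def test_p2plane_recovers_pose_from_coarse_init(self, template_478):
        src = template_478[0].points
        M = similarity_transform(1.0, (4, 12, -6))
        tgt = M.apply(src)
        coarse = global_registration(src, tgt)
        T, rmse = icp_point_to_plane(src, tgt, estimate_normals(tgt, 12), coarse)
        assert rmse < 1e-6

    def test_p2plane_no_overlap_raises(self, template_478):
        src = template_478[0].points
        tgt = src + 100.0  # ten+ diagonals away
        cfg = RegistrationConfig(icp_max_correspondence_distance=0.01)
        with pytest.raises(NoOverlapError):
            icp_point_to_plane(src, tgt, estimate_normals(tgt, 12), HomogeneousTransform.identity(), cfg)

    def test_p2p_identity_on_equal_clouds(self, template_478):
        src = template_478[0].points
        T, rmse = icp_point_to_point(src, src, HomogeneousTransform.identity())
        assert rmse < 1e-12
        assert np.allclose(T.matrix, np.eye(4), atol=1e-9)

    def test_p2p_pure_translation_converges_immediately(self, template_478):
        src = template_478[0].points
        tgt = src + np.array([0.005, -0.003, 0.002])
        cfg = RegistrationConfig(icp_max_iterations=2)
        T, rmse = icp_point_to_point(src, tgt, HomogeneousTransform.identity(), cfg)
        assert rmse < 1e-12
        assert np.allclose(T.translation, [0.005, -0.003, 0.002], atol=1e-10)

    def test_p2p_rotated_cloud_recovery(self, template_478):
        src = template_478[0].points
        M = similarity_transform(1.0, (0, 8, 0))
        tgt = M.apply(src)
        T, rmse = icp_point_to_point(src, tgt, HomogeneousTransform.identity())
        assert rmse < 1e-6
        assert np.abs(T.matrix - M.matrix).max() < 1e-6


class TestRegisterSweep:
    def test_source_equals_target(self, template_478, fast_cfg):
        src = template_478[0]
        res = register(src, src, fast_cfg)
        assert res.inlier_rmse <= 1e-6
        assert res.scale_factor == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_similarity_recovery(self, template_478, fast_cfg):
        src = template_478[0]
        M = similarity_transform(1.15, (5, 15, -3))
        tgt = src.with_points(M.apply(src.points))
        res = register(src, tgt, fast_cfg)
        assert res.inlier_rmse < 1e-5
        assert np.abs(res.transform.matrix - M.matrix).max() < 1e-3

    def test_translation_breaks_exact_scale_matching_but_stays_bounded(
        self, template_478, fast_cfg
    ):
        # origin-anchored scale matching is only approximate once the pose
        # includes a translation: recovery is no longer exact, but must stay
        # far below the raw misalignment
        src = template_478[0]
        M = similarity_transform(1.1, (0, 10, 0), (0.03, -0.02, 0.01))
        tgt = src.with_points(M.apply(src.points))
        res = register(src, tgt, fast_cfg)
        before, _ = inlier_rmse(src.points, tgt.points, HomogeneousTransform.identity())
        after, _ = inlier_rmse(src.points, tgt.points, res.transform)
        assert after < 0.05 * before

    def test_reported_rmse_is_sweep_minimum(self, template_478, fast_cfg, rng):
        src = template_478[0]
        tgt = src.with_points(
            similarity_transform(0.9, (0, 12, 0)).apply(src.points)
            + 0.005 * rng.standard_normal((478, 3))
        )
        res = register(src, tgt, fast_cfg)
        assert res.sweep_trace
        assert res.inlier_rmse == pytest.approx(min(r for _, r in res.sweep_trace), abs=1e-15)
        assert res.per_landmark_residuals.shape == (478,)

    def test_noisy_register_close_to_oracle(self, template_478, rng):
        src = template_478[0]
        sigma = 0.005
        M = similarity_transform(1.08, (3, -14, 6))
        tgt = src.with_points(M.apply(src.points) + sigma * rng.standard_normal((478, 3)))
        res = register(src, tgt, RegistrationConfig(sweep_stride=20))
        target_frame_rmse, _ = inlier_rmse(src.points, tgt.points, res.transform)
        _, oracle = umeyama_similarity(src.points, tgt.points)
        assert target_frame_rmse <= 2 * sigma
        assert target_frame_rmse <= 1.25 * oracle

    def test_mode_mismatch_rejected(self, template_478, template_68, fast_cfg):
        with pytest.raises(ValidationError):
            register(template_478[0], template_68[0], fast_cfg)
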