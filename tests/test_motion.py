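"""Euler transforms, anatomical frame, ICP and the two-stage motion pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from dentalseg.landmarks import LandmarkSet, read_landmarks, write_landmarks
from dentalseg.motion import (
    ICPParams,
    MotionParameters,
    RigidTransform,
    build_frame,
    compose_transform,
    decompose_transform,
    estimate_tooth_motions,
    icp,
    rotation_angle_deg,
)
from dentalseg.synthetic import ArchParams, apply_tooth_motion, generate_arch


class TestComposeDecompose:
    def test_zero_parameters_give_identity(self):
        H = compose_transform(MotionParameters(0, 0, 0, 0, 0, 0))
        np.testing.assert_allclose(H.matrix, np.eye(4), atol=1e-15)

    def test_translation_only_structure(self):
        H = compose_transform(MotionParameters(0, 0, 0, 1.5, -2.0, 3.0))
        np.testing.assert_allclose(H.rotation, np.eye(3), atol=1e-15)
        np.testing.assert_allclose(H.translation, [1.5, -2.0, 3.0])

    def test_z_rotation_against_matrix_exponential(self):
        """alpha=90 deg about z, clockwise-positive convention:
        equals expm(-alpha L_z) with the standard so(3) generator."""
        H = compose_transform(MotionParameters(90.0, 0, 0, 0, 0, 0))
        Lz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(H.rotation, expm(-np.pi / 2 * Lz), atol=1e-12)
        # x-hat maps to -y-hat under the clockwise convention
        np.testing.assert_allclose(H.rotation @ [1, 0, 0], [0, -1, 0], atol=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-179, 179), st.floats(-85, 85), st.floats(-179, 179),
           st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50))
    def test_roundtrip_property(self, a, b, g, tx, ty, tz):
        p = MotionParameters(a, b, g, tx, ty, tz)
        q = decompose_transform(compose_transform(p))
        np.testing.assert_allclose(q.as_array(), p.as_array(), atol=1e-9)

    def test_reconstruction_on_haar_rotations(self):
        from scipy.stats import special_ortho_group

        for i in range(50):
            R = special_ortho_group.rvs(3, random_state=i)
            H = RigidTransform.from_rotation_translation(R, [1.0, 2.0, 3.0])
            H2 = compose_transform(decompose_transform(H))
            np.testing.assert_allclose(H2.matrix, H.matrix, atol=1e-9)

    @pytest.mark.parametrize("beta", [90.0, -90.0])
    def test_gimbal_branch_flags_and_reconstructs(self, beta):
        H = compose_transform(MotionParameters(33.0, beta, 21.0, 1, 2, 3))
        q = decompose_transform(H)
        assert q.gimbal_lock
        assert q.gamma == 0.0
        np.testing.assert_allclose(compose_transform(q).matrix, H.matrix, atol=1e-9)

    def test_beta_never_exceeds_90(self):
        rng = np.random.default_rng(0)
        from scipy.stats import special_ortho_group

        for i in range(20):
            R = special_ortho_group.rvs(3, random_state=100 + i)
            q = decompose_transform(RigidTransform.from_rotation_translation(R, rng.normal(size=3)))
            assert abs(q.beta) <= 90.0 + 1e-9


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        H = np.eye(4)
        H[0, 0] = -1.0  # reflection
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(H)

    def test_inverse_and_compose(self):
        p = MotionParameters(25, -40, 10, 1, 2, 3)
        H = compose_transform(p)
        np.testing.assert_allclose((H @ H.inverse()).matrix, np.eye(4), atol=1e-12)


def canonical_landmarks(papilla=(3.0, 0.5, -2.0)):
    """Occlusal plane = z=0, raphae along +x below it, incisor anterior (+x)."""
    return LandmarkSet(
        molar_cusp_left=(-8.0, 10.0, 0.0),
        molar_cusp_right=(-8.0, -10.0, 0.0),
        incisor_edge=(12.0, 0.0, 0.0),
        raphae_points=np.array([
            [3.0, 0.0, -2.0], [6.0, 0.0, -2.5], [9.0, 0.0, -2.0]
        ]),
    )


class TestBuildFrame:
    def test_canonical_landmarks_give_identity_axes(self):
        lm = canonical_landmarks()
        f = build_frame(lm)
        np.testing.assert_allclose(f.axes, np.eye(3), atol=1e-12)
        # origin: papilla projected onto z=0
        np.testing.assert_allclose(f.origin, [3.0, 0.0, 0.0], atol=1e-12)

    def test_axes_orthonormal_right_handed(self, small_arch):
        _, lm = small_arch
        f = build_frame(lm)
        np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(f.axes) > 0.999999999

    def test_z_normal_to_occlusal_plane(self, small_arch):
        _, lm = small_arch
        z = build_frame(lm).axes[2]
        occ = lm.occlusal_points
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.dot(z, occ[i] - occ[j])) < 1e-9

    def test_z_points_away_from_palate(self, small_arch):
        _, lm = small_arch
        f = build_frame(lm)
        assert np.dot(f.axes[2], lm.raphae_points.mean(axis=0) - f.origin) <= 0

    def test_collinear_occlusal_points_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet((0, 0, 0), (1, 0, 0), (2, 0, 0),
                        np.array([[0, 1, 0], [0, 2, 0], [0, 3, 0]]))

    def test_landmark_file_roundtrip(self, tmp_path, small_arch):
        _, lm = small_arch
        p = tmp_path / "lm.txt"
        write_landmarks(lm, p)
        back = read_landmarks(p)
        np.testing.assert_allclose(back.all_points, lm.all_points, atol=1e-7)


class TestICP:
    def test_identical_clouds_give_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(80, 3))
        res = icp(pts, pts)
        np.testing.assert_allclose(res.transform.matrix, np.eye(4), atol=1e-9)
        assert res.rms < 1e-12

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(120, 3))
        true = compose_transform(MotionParameters(10.0, 0, 0, 1.0, 2.0, 3.0))
        res = icp(src, true.apply(src))
        np.testing.assert_allclose(res.transform.matrix, true.matrix, atol=1e-6)

    def test_error_decreases_with_iterations(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(150, 3)) * [3, 2, 1]
        true = compose_transform(MotionParameters(8.0, 4.0, -6.0, 0.5, -0.3, 0.2))
        tgt = true.apply(src)
        errs = []
        for k in (1, 3, 8, 40):
            res = icp(src, tgt, ICPParams(max_iter=k, tol=0.0))
            errs.append(rotation_angle_deg(res.transform.rotation @ true.rotation.T))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-6

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            icp(np.zeros((2, 3)), np.eye(3))
        line = np.outer(np.arange(10), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            icp(line, line)


class TestEstimateToothMotions:
    def test_no_motion_gives_zero_parameters(self, small_arch):
        mesh, lm = small_arch
        report = estimate_tooth_motions(mesh, mesh.copy(), lm, lm)
        assert not report.unmatched
        for tm in report.teeth.values():
            np.testing.assert_allclose(tm.params.as_array(), np.zeros(6), atol=1e-6)

    def test_missing_rugae_is_an_error(self, small_arch):
        mesh, _ = small_arch
        bare = mesh.copy()
        bare.label[bare.label == 17] = 0
        with pytest.raises(ValueError, match="rugae"):
            estimate_tooth_motions(bare, mesh)

    def test_equivariance_under_global_motion(self, small_arch):
        """Rigidly moving BOTH scans leaves every per-tooth parameter
        unchanged: the rugae anchor cancels global pose."""
        mesh, lm = small_arch
        motions = {
            6: compose_transform(MotionParameters(5.0, -3.0, 2.0, 1.0, 0.5, -0.8)),
            9: compose_transform(MotionParameters(-8.0, 2.0, 4.0, -0.5, 1.5, 0.3)),
        }
        post = apply_tooth_motion(mesh, motions)
        base = estimate_tooth_motions(mesh, post, lm, lm)

        G = compose_transform(MotionParameters(30.0, 10.0, -20.0, 8.0, -5.0, 12.0))
        pre_g = mesh.copy()
        pre_g.vertices = G.apply(mesh.vertices)
        post_g = post.copy()
        post_g.vertices = G.apply(post.vertices)
        lm_g = lm.transformed(G)
        moved = estimate_tooth_motions(pre_g, post_g, lm_g, lm_g)
        for lid in (6, 9):
            np.testing.assert_allclose(
                moved.teeth[lid].params.as_array(),
                base.teeth[lid].params.as_array(), atol=1e-5,
            )

    def test_tooth_in_one_scan_only_is_unmatched(self):
        pre, _ = generate_arch(ArchParams(n_teeth=4, seed=2, mesh_resolution=1200))
        post = pre.copy()
        drop = 2  # left lateral incisor
        post.label[post.label == drop] = 0
        report = estimate_tooth_motions(pre, post)
        assert drop in report.unmatched
        assert drop not in report.teeth

    def test_report_table_has_one_row_per_tooth(self, small_arch):
        mesh, lm = small_arch
        report = estimate_tooth_motions(mesh, mesh.copy(), lm, lm)
        frame = report.to_frame()
        assert len(frame) == len(report.teeth) == 14
        assert list(frame.columns) == [
            "label_id", "label", "alpha_deg", "beta_deg", "gamma_deg",
            "Tx_mm", "Ty_mm", "Tz_mm", "icp_rms_mm",
        ]
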