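"""Rigid registration cascade: landmarks, centrelines, ICP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rvotshape.geometry import nearest_on_surface
from rvotshape.centerline import compute_centreline
from rvotshape.measurements import extract_landmarks, GeometricSummary
from rvotshape.registration import (
    RigidTransform,
    select_reference,
    fit_rigid_points,
    fit_rigid_centrelines,
    icp,
    register_subject,
    register_population,
)


def random_rigid(seed=0, angle_deg=25.0, shift=8.0):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    t = rng.normal(scale=shift, size=3)
    return RigidTransform(R, t)


def summary(sa, l, d):
    return GeometricSummary(sa=sa, l_rvot=l, profile=np.array([[1.0, d]]), d_ave=d)


class TestRigidTransform:
    def test_proper_rigid_invariants(self):
        T = random_rigid(3)
        R = T.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self):
        T = random_rigid(1)
        I = T.compose(T.inverse())
        assert I.angle() < 1e-12
        assert np.linalg.norm(I.translation) < 1e-9


class TestSelectReference:
    def test_identical_population_tie_breaks_to_first(self):
        s = [summary(5000, 50, 25)] * 4
        assert select_reference(s) == 0

    def test_middle_subject_selected(self):
        s = [summary(5000, 50, 25), summary(7000, 50, 25), summary(9000, 50, 25)]
        assert select_reference(s) == 1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        s = [
            summary(rng.uniform(4e3, 1e4), rng.uniform(40, 80), rng.uniform(18, 32))
            for _ in range(15)
        ]
        X = np.array([[x.sa, x.l_rvot, x.d_ave] for x in s])
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = int(np.argmin(np.linalg.norm(z, axis=1)))
        assert select_reference(s) == oracle


class TestFitRigidPoints:
    def test_identity_when_already_aligned(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        T = fit_rigid_points(pts, pts)
        assert T.angle() < 1e-12 and np.linalg.norm(T.translation) < 1e-12

    def test_exact_recovery_of_known_motion(self):
        pts = np.random.default_rng(1).normal(size=(5, 3)) * 10
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        moved = pts @ R.T + t
        T = fit_rigid_points(pts, moved)
        assert np.allclose(T.rotation, R, atol=1e-9)
        assert np.allclose(T.translation, t, atol=1e-9)

    def test_noisy_correspondence_residual(self):
        """Monte-Carlo: sigma=0.1 mm noise leaves RMS residual <= 0.2 mm."""
        base = np.random.default_rng(2).normal(size=(10, 3)) * 20
        sq = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T_true = random_rigid(seed)
            noisy = T_true.apply(base) + rng.normal(0, 0.1, base.shape)
            T = fit_rigid_points(base, noisy)
            sq.append(((T.apply(base) - noisy) ** 2).sum(axis=1).mean())
        assert np.sqrt(np.mean(sq)) <= 0.2

    def test_collinear_configuration_rejected(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            fit_rigid_points(pts, pts + 1.0)


class TestFitRigidCentrelines:
    def test_identical_centrelines_identity(self, default_centreline):
        T = fit_rigid_centrelines(default_centreline, default_centreline)
        assert T.angle() < 1e-9
        assert np.linalg.norm(T.translation) < 1e-9

    def test_rigidly_moved_copy_recovered(self, default_centreline):
        T_true = random_rigid(7)
        moved = default_centreline.transformed(T_true.rotation, T_true.translation)
        T = fit_rigid_centrelines(moved, default_centreline)
        err = T.compose(T_true)
        assert err.angle() < 1e-6
        assert np.linalg.norm(err.translation) < 1e-6

    def test_different_calibre_same_axis_aligns_axes(self, cylinder):
        from rvotshape import synthetic as syn

        thin = syn.generate_shape(
            syn.ShapeParams(
                r_inlet=5.0, taper=0.0, bulge_amp=0.0, curv_frontal=0.0,
                curv_sagittal=0.0, inlet_ellipticity=1.0, trunk_length=50.0,
            ),
            suppress_branches=True,
        )[1]
        T_true = random_rigid(9, angle_deg=20)
        moved = thin.transformed(T_true.rotation, T_true.translation)
        T = fit_rigid_centrelines(moved, cylinder[1])
        tang_fixed = cylinder[1].trunk.points[-1] - cylinder[1].trunk.points[0]
        tang = T.rotation @ (moved.trunk.points[-1] - moved.trunk.points[0])
        cos = (tang @ tang_fixed) / np.linalg.norm(tang) / np.linalg.norm(tang_fixed)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 1.0


class TestICP:
    def test_identity_on_identical_meshes(self, default_shape):
        mesh, _, _ = default_shape
        T, d, trace = icp(mesh, mesh)
        assert d < 1e-9
        assert T.angle() < 1e-9

    def test_small_rotation_recovered(self, default_shape):
        mesh, _, _ = default_shape
        R = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        moved = RigidTransform(R, np.zeros(3)).apply_mesh(mesh)
        T, d, trace = icp(moved, mesh, max_iter=60)
        assert d < 0.05

    def test_distance_trace_non_increasing(self, default_shape):
        mesh, _, _ = default_shape
        R = Rotation.from_euler("x", 8, degrees=True).as_matrix()
        moved = RigidTransform(R, np.array([2.0, 0, 0])).apply_mesh(mesh)
        _, _, trace = icp(moved, mesh, max_iter=40)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_invalid_inputs(self, default_shape):
        mesh, _, _ = default_shape
        with pytest.raises(ValueError):
            icp(mesh, mesh, tol=0.0)


class TestRegisterPopulation:
    @pytest.fixture(scope="class")
    def rigid_copies(self, default_shape):
        mesh, _, _ = default_shape
        cl = compute_centreline(mesh, step=1.5)
        lm = extract_landmarks(cl)
        shapes, cls, lms, truths = [], [], [], []
        for i in range(3):
            T = RigidTransform.identity() if i == 0 else random_rigid(40 + i)
            m = T.apply_mesh(mesh)
            m.boundary_labels = dict(mesh.boundary_labels)
            shapes.append(m)
            cls.append(cl.transformed(T.rotation, T.translation))
            lms.append(lm.transformed(T.rotation, T.translation))
            truths.append(T)
        return shapes, cls, lms, truths

    def test_cascade_recovers_known_motions(self, rigid_copies):
        shapes, cls, lms, truths = rigid_copies
        registered, transforms = register_population(shapes, cls, lms, 0)
        for T, T_true in zip(transforms[1:], truths[1:]):
            err = T.compose(T_true)
            assert err.angle() < 1e-2
            assert np.linalg.norm(err.translation) < 0.1

    def test_reference_unchanged(self, rigid_copies):
        shapes, cls, lms, _ = rigid_copies
        registered, transforms = register_population(shapes, cls, lms, 0)
        assert transforms[0].angle() == 0.0
        assert np.array_equal(registered[0].vertices, shapes[0].vertices)

    def test_pairwise_surface_distances_small(self, rigid_copies):
        shapes, cls, lms, _ = rigid_copies
        registered, _ = register_population(shapes, cls, lms, 0)
        ref = registered[0]
        for m in registered[1:]:
            d = nearest_on_surface(ref, m.vertices[::7])[1]
            assert d.mean() < 0.1

    def test_cascade_is_idempotent_within_tolerance(self, rigid_copies):
        shapes, cls, lms, _ = rigid_copies
        registered, t1 = register_population(shapes, cls, lms, 0)
        cls2 = [c.transformed(T.rotation, T.translation) for c, T in zip(cls, t1)]
        lms2 = [l.transformed(T.rotation, T.translation) for l, T in zip(lms, t1)]
        _, t2 = register_population(registered, cls2, lms2, 0)
        for T in t2:
            assert T.angle() < 1e-3
            assert np.linalg.norm(T.translation) < 0.1

    def test_all_outputs_proper_rigid(self, rigid_copies):
        shapes, cls, lms, _ = rigid_copies
        _, transforms = register_population(shapes, cls, lms, 0)
        for T in transforms:
            R = T.rotation
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
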