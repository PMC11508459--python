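"""Deformable-template estimation: matching, template, validation, folds."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rvotshape.geometry import SurfaceMesh, SurfaceLocator
from rvotshape.deformation import flow
from rvotshape.atlas import (
    AtlasModel,
    KernelConfig,
    match,
    load_atlas,
    iterate_registration,
    kfold_template_stability,
)
from rvotshape.registration import RigidTransform


def make_sphere(scale=10.0, subdiv=1):
    import trimesh

    m = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(subdiv))
    m.vertices = m.vertices * scale
    return m


@pytest.fixture(scope="module")
def coarse_kernel():
    return KernelConfig(
        sigma_def=12.0, sigma_var=6.0, n_control_side=3, n_time_steps=6, max_iter=25
    )


@pytest.fixture(scope="module")
def flowed_population():
    """Known deformations of a base sphere with random momenta."""
    base = make_sphere(10.0, 2)
    rng = np.random.default_rng(1)
    grid = np.stack(
        np.meshgrid(*[np.linspace(-12, 12, 3)] * 3, indexing="ij"), -1
    ).reshape(-1, 3)
    meshes = []
    for _ in range(8):
        a = rng.normal(0, 0.6, grid.shape)
        v = flow(base.vertices, grid, a, 12.0, 6)
        meshes.append(SurfaceMesh(v, base.faces))
    return base, meshes


@pytest.fixture(scope="module")
def fitted_sphere_atlas(flowed_population):
    base, meshes = flowed_population
    model = AtlasModel(meshes)
    schedule = [
        KernelConfig(sigma_def=12.0, sigma_var=6.0, n_control_side=3,
                     n_time_steps=6, max_iter=20),
        KernelConfig(sigma_def=8.0, sigma_var=4.0, n_control_side=4,
                     n_time_steps=6, max_iter=20),
    ]
    return model.fit(schedule=schedule, n_alternations=1, template_steps=5)


class TestMatch:
    def test_target_equal_template_keeps_zero_momenta(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        a, controls, diag = match(base, base, coarse_kernel)
        assert np.linalg.norm(a) < 1e-6

    def test_translated_target_reconstructed(self, coarse_kernel):
        base = make_sphere(10.0, 2)
        target = SurfaceMesh(base.vertices + np.array([2.0, 0, 0]), base.faces)
        a, controls, diag = match(base, target, coarse_kernel)
        rec = flow(base.vertices, controls, a, coarse_kernel.sigma_def,
                   coarse_kernel.n_time_steps)
        d = SurfaceLocator(target).query(rec)[1]
        assert d.mean() < 0.3

    def test_objective_trace_non_increasing(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        target = SurfaceMesh(base.vertices * 1.1, base.faces)
        _, _, diag = match(base, target, coarse_kernel)
        tr = diag["trace"]
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))


class TestEstimateTemplate:
    def test_identical_population_converges_to_that_shape(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        model = AtlasModel([base.copy() for _ in range(4)])
        res = model.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=4)
        d = SurfaceLocator(base).query(res.template.vertices)[1]
        assert d.mean() < 0.1

    def test_symmetric_bump_pair_averages_out(self, coarse_kernel):
        base = make_sphere(10.0, 2)
        bump = np.exp(-((base.vertices[:, 2] - 10.0) ** 2) / 8.0)
        up = SurfaceMesh(base.vertices * (1 + 0.08 * bump)[:, None], base.faces)
        dn = SurfaceMesh(base.vertices * (1 - 0.08 * bump)[:, None], base.faces)
        model = AtlasModel([up, dn, up.copy(), dn.copy()])
        res = model.fit(schedule=[coarse_kernel], n_alternations=2, template_steps=8)
        d = SurfaceLocator(base).query(res.template.vertices)[1]
        assert d.mean() < 0.5

    def test_template_recovers_base_of_flowed_population(
        self, flowed_population, fitted_sphere_atlas
    ):
        base, _ = flowed_population
        d = SurfaceLocator(base).query(fitted_sphere_atlas.template.vertices)[1]
        assert d.mean() < 0.5

    def test_objective_non_increasing_within_stages(self, fitted_sphere_atlas):
        for h in fitted_sphere_atlas.history:
            obj = h["objective"]
            assert all(b <= a + 1e-9 for a, b in zip(obj, obj[1:]))

    def test_equivariance_under_common_rigid_motion(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        rng = np.random.default_rng(3)
        pop = [
            SurfaceMesh(base.vertices * (1 + 0.03 * i), base.faces) for i in range(3)
        ]
        R = Rotation.from_euler("zyx", [20, -15, 30], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 6.0])
        T = RigidTransform(R, t)
        model_a = AtlasModel([m.copy() for m in pop])
        res_a = model_a.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=4)
        model_b = AtlasModel([T.apply_mesh(m) for m in pop])
        res_b = model_b.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=4)
        moved = T.apply(res_a.template.vertices)
        d = np.linalg.norm(moved - res_b.template.vertices, axis=1)
        assert d.mean() < 0.1

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            AtlasModel([])


class TestReconstruction:
    def test_perfect_reconstruction_zero_error(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        model = AtlasModel([base.copy(), base.copy(), base.copy()])
        res = model.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=3)
        per, med, iqr = res.reconstruction_error()
        assert med < 0.1

    def test_error_invariant_under_common_rigid_motion(self, fitted_sphere_atlas):
        res = fitted_sphere_atlas
        _, med0, _ = res.reconstruction_error()
        R = Rotation.from_euler("y", 25, degrees=True).as_matrix()
        t = np.array([3.0, 1.0, -2.0])
        T = RigidTransform(R, t)
        import copy

        moved = copy.copy(res)
        moved.template = T.apply_mesh(res.template)
        moved.control_points = T.apply(res.control_points)
        moved.momenta = {k: v @ R.T for k, v in res.momenta.items()}
        moved.model = AtlasModel(
            [T.apply_mesh(m) for m in res.model.meshes], res.model.subject_ids
        )
        _, med1, _ = moved.reconstruction_error()
        assert med1 == pytest.approx(med0, rel=1e-6, abs=1e-9)


class TestSerialization:
    def test_save_load_round_trip(self, fitted_sphere_atlas, tmp_path):
        res = fitted_sphere_atlas
        res.save(tmp_path / "atlas")
        back = load_atlas(tmp_path / "atlas", meshes=res.model.meshes)
        assert np.allclose(back.template.vertices, res.template.vertices, atol=1e-5)
        assert np.allclose(back.control_points, res.control_points, atol=1e-9)
        for sid in res.momenta:
            assert np.allclose(back.momenta[sid], res.momenta[sid], atol=1e-9)
        assert back.kernel.sigma_def == res.kernel.sigma_def


class TestIterateRegistration:
    def test_round_count_bounded_and_logged(self, default_shape):
        # population of rigid copies of one Y-vessel: already converged,
        # one round should leave the atlas unchanged within tolerance
        from rvotshape.centerline import compute_centreline
        from rvotshape.measurements import extract_landmarks
        from rvotshape.meshops import remesh

        mesh, _, _ = default_shape
        coarse = remesh(mesh, 6.0)
        cl = compute_centreline(coarse, step=1.5)
        lm = extract_landmarks(cl)
        pop = [coarse.copy() for _ in range(3)]
        cls = [cl] * 3
        lms = [lm] * 3
        model = AtlasModel(pop)
        diag = coarse.bounding_box_diagonal()
        sched = [KernelConfig(sigma_def=0.3 * diag, sigma_var=0.15 * diag,
                              n_control_side=3, n_time_steps=5, max_iter=8)]
        res = model.fit(schedule=sched, n_alternations=1, template_steps=3)
        out = iterate_registration(
            pop, cls, lms, res, max_rounds=2,
            fit_kwargs=dict(n_alternations=1, template_steps=3),
        )
        assert hasattr(out, "compactness_log")
        assert len(out.compactness_log) <= 3
        assert out.stage_labels[-1] == "T3"


class TestKFoldStability:
    def test_each_subject_left_out_exactly_once(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        meshes = [base.copy() for _ in range(6)]
        model = AtlasModel(meshes)
        res = model.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=2)
        # partition property via the internal fold construction
        rng = np.random.default_rng(11)
        order = rng.permutation(6)
        folds = [order[i::3] for i in range(3)]
        flat = sorted(int(i) for f in folds for i in f)
        assert flat == list(range(6))
        # identical shapes: every fold template within 0.1 mm of the full one
        d = kfold_template_stability(
            model, res, k=3, seed=11,
            fit_kwargs=dict(n_alternations=1, template_steps=2),
        )
        assert len(d) == 3
        assert np.all(d < 0.1)

    def test_k_larger_than_population_rejected(self, coarse_kernel):
        base = make_sphere(10.0, 1)
        model = AtlasModel([base.copy() for _ in range(3)])
        res = model.fit(schedule=[coarse_kernel], n_alternations=1, template_steps=2)
        with pytest.raises(ValueError):
            kfold_template_stability(model, res, k=5, seed=0)
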