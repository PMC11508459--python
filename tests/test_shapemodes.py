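"""PCA shape modes over per-subject momenta."""

import numpy as np
import pytest

from rvotshape.geometry import SurfaceMesh
from rvotshape.atlas import AtlasModel, AtlasResults, KernelConfig
from rvotshape.shapemodes import ShapeModePCA, ShapeModeResults


def synthetic_atlas(momenta_rows, template=None, controls=None, sigma=12.0):
    """Assemble an AtlasResults directly from a momenta matrix (n, d)."""
    import trimesh

    X = np.asarray(momenta_rows, float)
    n, d = X.shape
    n_cp = d // 3
    if template is None:
        template = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(1))
        template.vertices = template.vertices * 10
    if controls is None:
        rng = np.random.default_rng(0)
        controls = rng.normal(0, 8, (n_cp, 3))
    ids = [f"S{i+1:03d}" for i in range(n)]
    model = AtlasModel([template.copy() for _ in range(n)], subject_ids=ids)
    kernel = KernelConfig(sigma_def=sigma, sigma_var=sigma / 2, n_time_steps=5)
    return AtlasResults(
        model=model,
        template=template,
        control_points=controls,
        momenta={sid: X[i].reshape(-1, 3) for i, sid in enumerate(ids)},
        kernel=kernel,
        schedule=[kernel],
        history=[],
        stage_labels=["T0", "T1"],
        init_index=0,
    )


class TestFitPCA:
    def test_rank_one_population_single_mode(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=30)
        direction /= np.linalg.norm(direction)
        X = np.outer(rng.normal(size=10), direction)
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        assert res.variance_fraction[0] > 0.99

    def test_two_factor_variance_split_recovered(self):
        rng = np.random.default_rng(1)
        d = 36
        u = np.zeros(d); u[0] = 1.0
        v = np.zeros(d); v[1] = 1.0
        n = 30
        a = rng.normal(0, np.sqrt(0.7), n)
        b = rng.normal(0, np.sqrt(0.3), n)
        X = np.outer(a, u) + np.outer(b, v)
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        assert abs(res.variance_fraction[0] - 0.7) < 0.05
        assert abs(res.variance_fraction[1] - 0.3) < 0.05

    def test_mean_subject_scores_are_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 24))
        X = np.vstack([X, X.mean(axis=0)])  # append the mean subject
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        assert np.allclose(res.scores[-1], 0.0, atol=1e-9)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 30))
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (len(X) - 1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1][: len(res.eigenvalues)]
        assert np.allclose(res.eigenvalues, eig, rtol=1e-8, atol=1e-10)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 27))
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        for i in range(len(X)):
            rec = res.reconstruct_vector(i)
            assert np.allclose(rec, X[i], rtol=1e-6, atol=1e-8)

    def test_basis_orthonormal_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 21))
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        G = res.modes @ res.modes.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-9)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_subjects_rejected(self):
        X = np.random.default_rng(6).normal(size=(2, 12))
        with pytest.raises(ValueError):
            ShapeModePCA(synthetic_atlas(X))

    def test_score_recovery_canonical_correlation(self):
        """k orthogonal generative factors: first k scores correlate > 0.9
        with the true factor coefficients."""
        rng = np.random.default_rng(7)
        d, n, k = 36, 40, 3
        basis = np.linalg.qr(rng.normal(size=(d, k)))[0].T
        coef = rng.normal(size=(n, k))
        coef = np.linalg.qr(coef - coef.mean(0))[0]  # sample-orthogonal factors
        coef = coef * np.sqrt(n - 1) * np.array([3.0, 2.0, 1.0])
        X = coef @ basis + rng.normal(0, 0.05, (n, d))
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        for j in range(k):
            r = np.max(np.abs(np.corrcoef(coef.T, res.scores[:, j])[k:, :k]))
            assert r > 0.9


class TestModeMesh:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 0.4, size=(8, 81))  # 27 control points
        rng2 = np.random.default_rng(9)
        controls = rng2.normal(0, 8, (27, 3))
        atlas = synthetic_atlas(X, controls=controls)
        return atlas, ShapeModePCA(atlas).fit()

    def test_zero_sd_returns_template_when_mean_removed(self, fitted):
        atlas, res = fitted
        # subtract the mean momenta so sd_multiple=0 flows with zero field
        res2 = ShapeModeResults(
            atlas=atlas,
            mean_vector=np.zeros_like(res.mean_vector),
            modes=res.modes,
            eigenvalues=res.eigenvalues,
            variance_fraction=res.variance_fraction,
            scores=res.scores,
            subject_ids=res.subject_ids,
        )
        m = res2.mode_mesh(0, 0.0)
        assert np.allclose(m.vertices, atlas.template.vertices, atol=1e-9)

    def test_plus_minus_2sd_symmetric_to_first_order(self, fitted):
        atlas, res = fitted
        t = atlas.template.vertices
        up = res.mode_mesh(0, 2.0).vertices - t
        dn = res.mode_mesh(0, -2.0).vertices - t
        base = res.mode_mesh(0, 0.0).vertices - t
        asym = np.linalg.norm((up - base) + (dn - base))
        scale = np.linalg.norm(up - base)
        assert asym < 0.25 * scale

    def test_modes_differ_pairwise(self, fitted):
        _, res = fitted
        m0 = res.mode_mesh(0, 2.0).vertices
        m1 = res.mode_mesh(1, 2.0).vertices
        assert np.linalg.norm(m0 - m1) > 1e-6

    def test_extrapolation_warns(self, fitted):
        _, res = fitted
        with pytest.warns(UserWarning, match="extrapolat"):
            res.mode_mesh(0, 6.0)


class TestSelectionAndCompactness:
    @pytest.fixture(scope="class")
    def graded(self):
        """Population whose variance fractions mirror a typical published
        spectrum (0.38, 0.14, 0.08, 0.08, 0.05, rest small)."""
        fracs = np.array([0.38, 0.14, 0.08, 0.08, 0.05, 0.04, 0.04, 0.04,
                          0.03, 0.03, 0.03, 0.03, 0.03])
        n, d = 60, 39
        rng = np.random.default_rng(10)
        # build data with exactly these sample-covariance eigenvalue shares:
        # orthonormal score directions centred on zero, scaled singular values
        U = rng.normal(size=(n, len(fracs)))
        U = U - U.mean(axis=0)
        U = np.linalg.qr(U)[0]
        V = np.linalg.qr(rng.normal(size=(d, len(fracs))))[0]
        s = np.sqrt(fracs * (n - 1))
        X = U @ np.diag(s) @ V.T
        res = ShapeModePCA(synthetic_atlas(X)).fit()
        return res

    def test_five_percent_rule_selects_first_five(self, graded):
        sel = graded.select_modes(0.05)
        assert sel == [0, 1, 2, 3, 4]

    def test_compactness_of_five_modes(self, graded):
        assert graded.compactness(5) == pytest.approx(0.73, abs=0.01)

    def test_threshold_edges(self, graded):
        assert graded.select_modes(0.0) == list(range(len(graded.variance_fraction)))
        assert graded.select_modes(1.0) == []

    def test_compactness_monotone_and_reaches_one(self, graded):
        vals = [graded.compactness(m) for m in range(1, len(graded.variance_fraction) + 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)

    def test_invalid_m_rejected(self, graded):
        with pytest.raises(ValueError):
            graded.compactness(0)
        with pytest.raises(ValueError):
            graded.compactness(10**6)
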