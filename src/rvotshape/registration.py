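"""Rigid registration cascade: landmarks → centrelines → ICP.

All transforms are proper rigid motions (rotation + translation, no
scaling or reflection): population size differences are a finding of the
shape analysis, not a nuisance to be normalised away.  The population is
aligned to the subject whose geometric variables (SA, L_RVOT, D_AVE) lie
closest to the population mean in z-score units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceMesh, SurfaceLocator
from .centerline import Centreline
from .measurements import GeometricSummary, LandmarkSet


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 (reflection?)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        out = mesh.copy()
        out.vertices = self.apply(mesh.vertices)
        return out

    def angle(self) -> float:
        """Rotation angle in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def select_reference(summaries: list[GeometricSummary]) -> int:
    """Index of the subject nearest the population mean in (SA, L, D) z-scores."""
    if len(summaries) < 2:
        raise ValueError("need at least two subjects")
    X = np.array([[s.sa, s.l_rvot, s.d_ave] for s in summaries])
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    norms = np.linalg.norm(z, axis=1)
    return int(np.argmin(norms))  # argmin takes the lowest index on ties


def fit_rigid_points(
    moving: np.ndarray, fixed: np.ndarray, allow_degenerate: bool = False
) -> RigidTransform:
    """Least-squares rigid fit of ordered point pairs (Kabsch/Umeyama).

    Minimises sum ||R m_i + t - f_i||²; reflections are excluded.
    Collinear configurations are rejected unless ``allow_degenerate`` is
    set, in which case one valid minimiser (axis-aligning, arbitrary roll)
    is returned.
    """
    m = np.asarray(moving, float)
    f = np.asarray(fixed, float)
    if m.shape != f.shape or len(m) < 3:
        raise ValueError("need equal counts of at least 3 points")
    mc = m.mean(axis=0)
    fc = f.mean(axis=0)
    H = (m - mc).T @ (f - fc)
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) configurations have rank < 2
    if not allow_degenerate and S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return RigidTransform(R, t)


def fit_rigid_centrelines(
    moving: Centreline, fixed: Centreline, samples_per_branch: int = 20
) -> RigidTransform:
    """Rigid fit on centrelines resampled to equal arc-length fractions.

    Points are paired by arc-length fraction within matching branch labels
    (trunk, lpa, rpa), then fitted as ordered correspondences.
    """
    mov_pts, fix_pts = [], []
    for name in ("trunk", "lpa", "rpa"):
        pm = moving.trunk if name == "trunk" else moving.branches()[name]
        pf = fixed.trunk if name == "trunk" else fixed.branches()[name]
        if len(pm.points) < 2 or len(pf.points) < 2:
            raise ValueError(f"empty branch {name}")
        mov_pts.append(pm.resample(samples_per_branch).points)
        fix_pts.append(pf.resample(samples_per_branch).points)
    # degenerate (stub-branch) centrelines are collinear; an axis-aligning
    # minimiser is still well-defined and wanted here
    return fit_rigid_points(
        np.vstack(mov_pts), np.vstack(fix_pts), allow_degenerate=True
    )


def icp(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-3,
    sample: int = 800,
    seed: int = 0,
):
    """Point-to-surface iterative closest point with rigid updates.

    Moving-mesh vertices (subsampled to ``sample``) are matched to their
    exact nearest points on the fixed surface each iteration.  Stops when
    the mean closest distance improves by less than ``tol`` mm; declares
    divergence after 5 consecutive increases and returns the best seen.

    Returns (transform, mean_distance, trace).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise ValueError("empty mesh")
    T = init or RigidTransform.identity()
    locator = SurfaceLocator(fixed)
    pts0 = moving.vertices
    if len(pts0) > sample:
        rng = np.random.default_rng(seed)
        pts0 = pts0[rng.choice(len(pts0), sample, replace=False)]
    best = (None, np.inf)
    prev = np.inf
    rising = 0
    trace = []
    for _ in range(max_iter):
        cur = T.apply(pts0)
        closest, dist, _ = locator.query(cur)
        mean_d = float(dist.mean())
        trace.append(mean_d)
        if mean_d < best[1]:
            best = (T, mean_d)
        if mean_d > prev + 1e-12:
            rising += 1
            if rising >= 5:
                warnings.warn("ICP diverging; returning best transform seen")
                T, mean_d = best
                break
        else:
            rising = 0
        if prev - mean_d < tol and np.isfinite(prev):
            break
        prev = mean_d
        step = fit_rigid_points(cur, closest)
        T = step.compose(T)
    return T, trace[-1] if trace else np.inf, trace


def register_subject(
    moving_mesh: SurfaceMesh,
    moving_centreline: Centreline,
    moving_landmarks: LandmarkSet,
    fixed_centreline: Centreline,
    fixed_landmarks: LandmarkSet,
    fixed_mesh: SurfaceMesh,
    samples_per_branch: int = 20,
    icp_kwargs: dict | None = None,
) -> RigidTransform:
    """Full cascade for one subject: landmarks, then centrelines, then ICP."""
    T1 = fit_rigid_points(moving_landmarks.as_array(), fixed_landmarks.as_array())
    cl1 = moving_centreline.transformed(T1.rotation, T1.translation)
    T2 = fit_rigid_centrelines(cl1, fixed_centreline, samples_per_branch).compose(T1)
    T3, _, _ = icp(moving_mesh, fixed_mesh, init=T2, **(icp_kwargs or {}))
    return T3


def register_population(
    shapes: list[SurfaceMesh],
    centrelines: list[Centreline],
    landmarks: list[LandmarkSet],
    reference_index: int,
    samples_per_branch: int = 20,
    icp_kwargs: dict | None = None,
):
    """Align every subject to the reference via the cascade.

    Returns (transformed meshes, transforms); the reference carries the
    identity transform.
    """
    n = len(shapes)
    if not (len(centrelines) == len(landmarks) == n):
        raise ValueError("inconsistent per-subject data")
    ref_mesh = shapes[reference_index]
    ref_cl = centrelines[reference_index]
    ref_lm = landmarks[reference_index]
    transforms = []
    out_meshes = []
    for i in range(n):
        if i == reference_index:
            T = RigidTransform.identity()
        else:
            T = register_subject(
                shapes[i],
                centrelines[i],
                landmarks[i],
                ref_cl,
                ref_lm,
                ref_mesh,
                samples_per_branch=samples_per_branch,
                icp_kwargs=icp_kwargs,
            )
        transforms.append(T)
        out_meshes.append(T.apply_mesh(shapes[i]))
        out_meshes[-1].boundary_labels = dict(shapes[i].boundary_labels)
    return out_meshes, transforms
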