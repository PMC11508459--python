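"""PCA shape modes of the deformation representation.

Per-subject momenta are flattened into vectors; principal component
analysis of their sample covariance yields the population's shape modes.
A subject's *shape vector* is its projection (score) on a mode; modes
capturing at least 5% of variance are retained for interpretation and
visualised by flowing the template at ±2 SD along each mode.  The
*compactness* of the model at m modes is the cumulative variance
fraction of the first m modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh
from .deformation import flow


class ShapeModePCA:
    """PCA model over a fitted atlas's per-subject momenta."""

    def __init__(self, atlas_results):
        self.atlas = atlas_results
        if len(atlas_results.model.subject_ids) < 3:
            raise ValueError("need at least 3 subjects for PCA")

    def fit(self) -> "ShapeModeResults":
        X = self.atlas.momenta_matrix()  # (n, d)
        n = len(X)
        mean = X.mean(axis=0)
        Xc = X - mean
        # economy SVD: eigenvalues of the (n-1)-denominator sample covariance
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        modes = Vt
        # fixed sign convention: each mode's largest-magnitude loading positive
        for i in range(len(modes)):
            j = int(np.argmax(np.abs(modes[i])))
            if modes[i, j] < 0:
                modes[i] = -modes[i]
        scores = Xc @ modes.T
        total = eigenvalues.sum()
        frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
        return ShapeModeResults(
            atlas=self.atlas,
            mean_vector=mean,
            modes=modes,
            eigenvalues=eigenvalues,
            variance_fraction=frac,
            scores=scores,
            subject_ids=list(self.atlas.model.subject_ids),
        )


@dataclass
class ShapeModeResults:
    """Eigen-decomposition of the shape-deformation covariance."""

    atlas: object
    mean_vector: np.ndarray
    modes: np.ndarray  # (k, d) orthonormal rows, descending variance
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: np.ndarray  # (n, k) per-subject shape vectors
    subject_ids: list

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")

    # -- mode interpretation ---------------------------------------------
    def mode_mesh(self, mode_index: int, sd_multiple: float) -> SurfaceMesh:
        """Template deformed along one mode at ``sd_multiple`` standard deviations."""
        if not (0 <= mode_index < len(self.modes)):
            raise IndexError("mode_index out of range")
        if abs(sd_multiple) > 5:
            import warnings

            warnings.warn("extrapolating beyond 5 SD from the mean")
        vec = self.mean_vector + sd_multiple * np.sqrt(
            self.eigenvalues[mode_index]
        ) * self.modes[mode_index]
        a = vec.reshape(-1, 3)
        at = self.atlas
        v = flow(
            at.template.vertices,
            at.control_points,
            a,
            at.kernel.sigma_def,
            at.kernel.n_time_steps,
        )
        return SurfaceMesh(v, at.template.faces.copy(), dict(at.template.boundary_labels))

    def select_modes(self, threshold: float = 0.05) -> list[int]:
        """Indices of modes whose variance fraction is at least ``threshold``."""
        return [i for i, f in enumerate(self.variance_fraction) if f >= threshold]

    def compactness(self, m: int) -> float:
        """Cumulative variance fraction of the first ``m`` modes."""
        if m < 1:
            raise ValueError("m must be >= 1")
        if m > len(self.variance_fraction):
            raise ValueError("m exceeds the number of modes")
        return float(self.variance_fraction[:m].sum())

    def reconstruct_vector(self, subject_index: int) -> np.ndarray:
        """Back-project a subject's scores through all modes (identity check)."""
        return self.mean_vector + self.scores[subject_index] @ self.modes

    # -- export -----------------------------------------------------------
    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"mode{i+1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def variance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                mode=np.arange(1, len(self.eigenvalues) + 1),
                eigenvalue=self.eigenvalues,
                variance_fraction=self.variance_fraction,
                cumulative=np.cumsum(self.variance_fraction),
            )
        )

    def summary(self) -> str:
        lines = ["Shape-mode PCA", "=" * 40]
        sel = self.select_modes()
        for i, f in enumerate(self.variance_fraction[: max(len(sel), 5)]):
            mark = "*" if i in sel else " "
            lines.append(
                f"mode {i+1:2d}{mark} variance {100*f:5.1f}%  cumulative "
                f"{100*self.variance_fraction[:i+1].sum():5.1f}%"
            )
        lines.append(f"modes >= 5% variance: {len(sel)}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        from pathlib import Path
        from .meshops import write_mesh

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.variance_frame().to_csv(d / "variance.csv", index=False)
        self.scores_frame().to_csv(d / "scores.csv", index=False)
        for i in self.select_modes():
            for sd in (-2, 0, 2):
                write_mesh(
                    self.mode_mesh(i, sd), d / f"mode{i+1}_sd{sd:+d}.ply"
                )
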