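"""Core surface-mesh container and exact nearest-point queries.

All coordinates are millimetres; face indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

#: canonical boundary-loop labels for a Y-shaped open vessel
LOOP_LABELS = ("inlet", "lpa", "rpa")


@dataclass
class SurfaceMesh:
    """Open triangulated surface with labelled boundary loops.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, 0-based vertex indices
    boundary_labels : dict mapping loop id (int) to one of
        ``inlet``/``lpa``/``rpa`` (or clip-generated labels).
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a missing vertex")

    # -- conversions -----------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, boundary_labels=None) -> "SurfaceMesh":
        return cls(
            np.asarray(tm.vertices, dtype=float),
            np.asarray(tm.faces, dtype=np.int64),
            dict(boundary_labels or {}),
        )

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), dict(self.boundary_labels)
        )

    # -- basic quantities ------------------------------------------------
    @property
    def face_normals_area(self) -> np.ndarray:
        """Per-face area-weighted normals (0.5 * edge cross product)."""
        v = self.vertices
        f = self.faces
        return 0.5 * np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    @property
    def area(self) -> float:
        return float(np.linalg.norm(self.face_normals_area, axis=1).sum())

    @property
    def face_centers(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def bounding_box_diagonal(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    # -- boundary topology -----------------------------------------------
    def boundary_edges(self) -> np.ndarray:
        """(k, 2) array of directed boundary edges (appear in one face only)."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return edges[counts[inv] == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex index cycles for each boundary loop.

        Loops are sorted by descending vertex count for stable ids.
        """
        edges = self.boundary_edges()
        nxt = {int(a): int(b) for a, b in edges}
        loops = []
        seen = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt.get(start)
            # guard against non-manifold boundary vertices: stop on revisit
            while cur is not None and cur != start and cur not in seen:
                loop.append(cur)
                seen.add(cur)
                cur = nxt.get(cur)
            loops.append(np.asarray(loop, dtype=np.int64))
        loops.sort(key=lambda l: (-len(l), int(l.min()) if len(l) else 0))
        return loops

    def loop_centroids(self) -> np.ndarray:
        return np.array([self.vertices[l].mean(axis=0) for l in self.boundary_loops()])

    def boundary_vertex_set(self) -> set:
        return set(int(v) for v in self.boundary_edges().ravel())

    def relabel_loops_from(self, other: "SurfaceMesh") -> None:
        """Assign this mesh's loop labels by nearest-centroid match to ``other``.

        Used after remeshing or rigid motion, where loop ids change but
        anatomy does not.
        """
        if not other.boundary_labels:
            return
        ours = self.loop_centroids()
        theirs = other.loop_centroids()
        labels = {}
        for lid, name in other.boundary_labels.items():
            if lid >= len(theirs):
                continue
            d = np.linalg.norm(ours - theirs[lid], axis=1)
            labels[int(np.argmin(d))] = name
        self.boundary_labels = labels

    def labelled_loop(self, name: str) -> np.ndarray:
        loops = self.boundary_loops()
        for lid, nm in self.boundary_labels.items():
            if nm == name:
                return loops[lid]
        raise KeyError(f"no boundary loop labelled {name!r}")

    def validate(self) -> None:
        if self.area <= 0:
            raise ValueError("mesh has non-positive total area")
        areas = np.linalg.norm(self.face_normals_area, axis=1)
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")


class SurfaceLocator:
    """Exact nearest point-on-triangle queries via a centroid KD-tree.

    Candidate triangles are taken as the k nearest by centroid plus any
    whose centroid lies within the best candidate bound; the exact
    point-triangle distance is then minimised over candidates.
    """

    def __init__(self, mesh: SurfaceMesh, k: int = 12):
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self.centers = self.tri.mean(axis=1)
        # circumscribing radius bound per triangle (max centroid-vertex dist)
        self.radius = np.linalg.norm(self.tri - self.centers[:, None, :], axis=2).max(
            axis=1
        )
        self.rmax = float(self.radius.max()) if len(self.radius) else 0.0
        self.tree = cKDTree(self.centers)
        self.k = min(k, len(self.centers))

    def query(self, points: np.ndarray):
        """Return (closest points (n,3), distances (n,), face indices (n,))."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d0, idx0 = self.tree.query(points, k=self.k)
        if self.k == 1:
            d0 = d0[:, None]
            idx0 = idx0[:, None]
        out_p = np.empty_like(points)
        out_d = np.empty(len(points))
        out_f = np.empty(len(points), dtype=np.int64)
        for i, p in enumerate(points):
            cand = idx0[i]
            # guarantee correctness: include every triangle whose centroid is
            # within best upper bound + its own radius
            ub = d0[i, 0] + self.rmax
            extra = self.tree.query_ball_point(p, ub)
            cand = np.unique(np.concatenate([cand, np.asarray(extra, dtype=np.int64)]))
            cp = _closest_point_on_triangles(self.tri[cand], p)
            dd = np.linalg.norm(cp - p, axis=1)
            j = int(np.argmin(dd))
            out_p[i] = cp[j]
            out_d[i] = dd[j]
            out_f[i] = cand[j]
        return out_p, out_d, out_f


def _closest_point_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle in ``tri`` ((m,3,3) → (m,3)).

    Vectorised Ericson-style region classification.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp_ = p - c
    d5 = (ab * cp_).sum(1)
    d6 = (ac * cp_).sum(1)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def nearest_on_surface(mesh: SurfaceMesh, points: np.ndarray, k: int = 12):
    """Convenience wrapper: exact nearest surface points for ``points``.

    Returns (closest_points, distances, face_indices).
    """
    return SurfaceLocator(mesh, k=k).query(points)
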