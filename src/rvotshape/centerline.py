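"""Centreline extraction and centreline-orthogonal clipping.

The centreline of the Y-shaped vessel is recovered by a plane-sweep march:
starting from the inlet opening, the mesh is intersected with a plane
orthogonal to the current marching direction; the centroid of the enclosing
cross-section curve becomes the next centreline point.  The maximal
inscribed-sphere radius at each point is the exact distance from the point
to the surface.  The bifurcation point is the last trunk point before the
cross-section splits into two closed curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from trimesh.intersections import mesh_plane, slice_mesh_plane

from .geometry import SurfaceMesh, SurfaceLocator


@dataclass
class Polyline:
    """Ordered 3D polyline with per-point inscribed-sphere radius (mm)."""

    points: np.ndarray
    radius: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float).ravel()

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1]) if len(self.points) > 1 else 0.0

    def resample(self, n: int) -> "Polyline":
        """Resample to ``n`` points at equal arc-length fractions."""
        s = self.arclength
        t = np.linspace(0.0, s[-1], n)
        pts = np.column_stack(
            [np.interp(t, s, self.points[:, i]) for i in range(3)]
        )
        rad = np.interp(t, s, self.radius)
        return Polyline(pts, rad)

    def point_at(self, s: float) -> np.ndarray:
        sl = self.arclength
        s = float(np.clip(s, sl[0], sl[-1]))
        return np.array([np.interp(s, sl, self.points[:, i]) for i in range(3)])

    def tangent_at(self, s: float) -> np.ndarray:
        sl = self.arclength
        s = float(np.clip(s, sl[0], sl[-1]))
        i = int(np.searchsorted(sl, s, side="right")) - 1
        i = min(max(i, 0), len(sl) - 2)
        d = self.points[i + 1] - self.points[i]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Polyline":
        return Polyline(self.points @ R.T + t, self.radius.copy())


@dataclass
class Centreline:
    """Y-shaped centreline: trunk plus two branch polylines.

    The trunk's last point is the bifurcation point, which is also the
    first point of each branch polyline.
    """

    trunk: Polyline
    branch_lpa: Polyline
    branch_rpa: Polyline
    bifurcation_point: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bifurcation_point is None:
            self.bifurcation_point = self.trunk.points[-1].copy()
        self.bifurcation_point = np.asarray(self.bifurcation_point, dtype=float)

    def branches(self):
        return {"lpa": self.branch_lpa, "rpa": self.branch_rpa}

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Centreline":
        return Centreline(
            self.trunk.transformed(R, t),
            self.branch_lpa.transformed(R, t),
            self.branch_rpa.transformed(R, t),
            self.bifurcation_point @ R.T + t,
        )

    def validate(self) -> None:
        for name, pl in [("trunk", self.trunk), ("lpa", self.branch_lpa), ("rpa", self.branch_rpa)]:
            if np.any(np.diff(pl.arclength) <= 0):
                raise ValueError(f"{name} arc-length not strictly increasing")
            if np.any(pl.radius <= 0):
                raise ValueError(f"{name} has non-positive inscribed radius")
        if not np.allclose(self.trunk.points[-1], self.bifurcation_point, atol=1e-9):
            raise ValueError("trunk last point is not the bifurcation point")


# ----------------------------------------------------------------------
# cross-section machinery


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return vt[-1]


def _section_components(mesh: SurfaceMesh, origin, normal, tm=None, _retries=2):
    """Intersect mesh with a plane; group segments into components.

    Returns list of dicts with keys: points (ordered if closed), closed,
    perimeter, centroid.  When the plane passes exactly through a mesh
    vertex the section graph grows nodes of degree > 2; the plane is then
    nudged slightly along its normal and recomputed.
    """
    tm = tm if tm is not None else mesh.to_trimesh()
    segs = mesh_plane(tm, np.asarray(normal, float), np.asarray(origin, float))
    if len(segs) == 0:
        return []
    # merge coincident segment endpoints by distance (robust to rounding)
    from scipy.spatial import cKDTree

    pts = segs.reshape(-1, 3)
    tree = cKDTree(pts)
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(1e-6):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(pts))])
    uniq_roots, inv = np.unique(roots, return_inverse=True)
    coords = np.zeros((len(uniq_roots), 3))
    counts = np.zeros(len(uniq_roots))
    np.add.at(coords, inv, pts)
    np.add.at(counts, inv, 1.0)
    coords /= counts[:, None]
    edges = inv.reshape(-1, 2)
    adj = {}
    for a, b in edges:
        if a == b:
            continue
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    if _retries > 0 and any(len(v) > 2 for v in adj.values()):
        # vertex-in-plane artifact: nudge the plane and recompute
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        return _section_components(
            mesh, np.asarray(origin, float) + 1e-3 * n, normal, tm=tm,
            _retries=_retries - 1,
        )
    seen = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack = [start]
        nodes = []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            nodes.append(u)
            stack.extend(v for v in adj[u] if v not in seen)
        closed = all(len(adj[u]) == 2 for u in nodes) and len(nodes) >= 3
        # order the component by walking (closed loop or open chain)
        if closed:
            ordered = _walk_cycle(adj, nodes)
        else:
            ordered = nodes
        p = coords[ordered]
        if closed:
            seglen = np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1)
        else:
            seglen = np.linalg.norm(np.diff(p, axis=0), axis=1) if len(p) > 1 else np.array([0.0])
        perim = float(seglen.sum())
        # length-weighted centroid of the curve
        if closed and perim > 0:
            mids = 0.5 * (p + np.roll(p, -1, axis=0))
            centroid = (mids * seglen[:, None]).sum(axis=0) / perim
        else:
            centroid = p.mean(axis=0)
        comps.append(
            dict(points=p, closed=closed, perimeter=perim, centroid=centroid)
        )
    return comps


def _walk_cycle(adj, nodes):
    start = nodes[0]
    ordered = [start]
    prev = None
    cur = start
    while True:
        nbrs = [v for v in adj[cur] if v != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
        if cur == start:
            break
        ordered.append(cur)
        if len(ordered) > len(nodes) + 1:
            break
    return ordered


def _turn_towards(d: np.ndarray, target: np.ndarray, max_angle: float) -> np.ndarray:
    """Rotate unit vector ``d`` towards ``target`` by at most ``max_angle``."""
    c = float(np.clip(d @ target, -1.0, 1.0))
    ang = np.arccos(c)
    if ang <= max_angle:
        return target
    axis = np.cross(d, target)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        return d
    axis = axis / na
    k = np.cross(axis, d)
    out = d * np.cos(max_angle) + k * np.sin(max_angle)
    return out / np.linalg.norm(out)


def _point_in_loop(loop_pts: np.ndarray, point: np.ndarray, normal: np.ndarray) -> bool:
    """Winding-number containment test in the section plane."""
    n = normal / np.linalg.norm(normal)
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = loop_pts - point
    x = rel @ e1
    y = rel @ e2
    # total signed turning of the loop around the point
    theta = np.arctan2(y, x)
    d = np.diff(np.concatenate([theta, theta[:1]]))
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return abs(d.sum() / (2 * np.pi)) > 0.5


def cross_section(mesh: SurfaceMesh, origin, normal, tm=None):
    """All cross-section components of the mesh at the given plane."""
    return _section_components(mesh, origin, normal, tm=tm)


# ----------------------------------------------------------------------
# plane-sweep centreline


def compute_centreline(mesh: SurfaceMesh, step: float = 1.0) -> Centreline:
    """Extract the Y-shaped centreline by a plane-sweep centroid march.

    Parameters
    ----------
    mesh : SurfaceMesh with boundary loops labelled inlet/lpa/rpa.
    step : marching step in mm (default 1).

    Raises
    ------
    ValueError if the march leaves the mesh or a section splits into more
    than two components.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    tm = mesh.to_trimesh()
    locator = SurfaceLocator(mesh)
    loops = mesh.boundary_loops()
    try:
        inlet_loop = mesh.labelled_loop("inlet")
    except KeyError as e:
        raise ValueError("mesh must have a labelled inlet opening") from e
    inlet_pts = mesh.vertices[inlet_loop]
    p0 = inlet_pts.mean(axis=0)
    n0 = _fit_plane_normal(inlet_pts)
    interior = mesh.vertices.mean(axis=0) - p0
    if interior @ n0 < 0:
        n0 = -n0

    opening_centroids = {
        name: mesh.vertices[mesh.labelled_loop(name)].mean(axis=0)
        for name in mesh.boundary_labels.values()
    }

    def inscribed(p):
        return float(locator.query(np.atleast_2d(p))[1][0])

    def march(start, direction, max_len, watch_split):
        """March until split / open section / exhaustion.

        Returns (points, final direction, state) where state is 'split'
        with the two components, 'open', or 'end'.
        """
        pts = [np.asarray(start, float)]
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        n_max = int(np.ceil(max_len / step)) + 4
        recent_r = []
        for _ in range(n_max):
            q = pts[-1] + step * d
            comps = _section_components(mesh, q, d, tm=tm)
            if len(pts) == 1 and not any(c["closed"] for c in comps):
                # a warped opening can stay in the cutting plane for a few
                # steps; advance until the first closed section
                for mult in (2, 3, 4, 5, 6):
                    q = pts[-1] + mult * step * d
                    comps = _section_components(mesh, q, d, tm=tm)
                    if any(c["closed"] for c in comps):
                        break
            # keep components near the marching point; the tube scale uses a
            # trailing maximum because the inscribed radius collapses at the
            # saddle just before the section splits
            recent_r.append(inscribed(pts[-1]))
            r_here = max(recent_r[-8:])
            local_r = r_here + 3.0 * step
            near = [
                c
                for c in comps
                if np.linalg.norm(c["centroid"] - q) < max(3 * local_r, 6 * step)
            ]
            if not near:
                return pts, d, ("end", None)
            closed = [c for c in near if c["closed"]]
            open_ = [c for c in near if not c["closed"]]

            def split_check(comps_at, origin):
                """Two comparable closed components near the axis = split;
                grazing slivers (< 30% of the largest perimeter) ignored."""
                big = sorted(
                    (
                        c
                        for c in comps_at
                        if c["closed"]
                        and c["perimeter"] > 2.0 * step
                        and np.linalg.norm(c["centroid"] - origin)
                        < 2.2 * r_here + 2 * step
                    ),
                    key=lambda c: -c["perimeter"],
                )
                major = [c for c in big if c["perimeter"] >= 0.3 * big[0]["perimeter"]] if big else []
                if len(major) > 2:
                    raise ValueError(
                        "cross-section split into more than two components"
                    )
                return major if len(major) == 2 else None

            if watch_split and len(closed) >= 2:
                major = split_check(closed, q)
                if major is not None:
                    return pts, d, ("split", (major, q))
            # enclosing component: contains the projection of q (restricted
            # to components plausibly belonging to the marched tube)
            cands = [
                c
                for c in closed
                if np.linalg.norm(c["centroid"] - q) < 1.5 * r_here + 2 * step
            ]
            if not cands:
                if watch_split:
                    # right at the bifurcation the section degenerates to a
                    # figure-eight through the saddle; probe a little further
                    for jj in (1, 2, 3):
                        q2 = q + jj * step * d
                        comps2 = _section_components(mesh, q2, d, tm=tm)
                        major = split_check(comps2, q2)
                        if major is not None:
                            return pts, d, ("split", (major, q2))
                return pts, d, ("open", open_)
            enc = None
            for c in cands:
                if _point_in_loop(c["points"], q, d):
                    enc = c
                    break
            if enc is None:
                enc = min(cands, key=lambda c: np.linalg.norm(c["centroid"] - q))
            # damp the lateral correction and bound the turn rate so that
            # oblique-section centroid bias cannot feed back into the
            # marching direction (tube curvature is ~1 deg/mm at most)
            new_pt = q + 0.6 * (enc["centroid"] - q)
            new_d = new_pt - pts[-1]
            nn = np.linalg.norm(new_d)
            new_d = d if nn < 1e-9 else new_d / nn
            d = _turn_towards(d, new_d, np.radians(5.0) * step)
            pts.append(new_pt)
        return pts, d, ("end", None)

    diag = mesh.bounding_box_diagonal()
    trunk_pts, d_end, (state, payload) = march(p0, n0, diag, watch_split=True)
    if state == "end" and len(trunk_pts) < 2:
        raise ValueError("cross-section empty: marched outside the mesh")

    if state == "split":
        bif = trunk_pts[-1]
        split_comps, q_split = payload
        # Track both branches by continuing the sweep along the trunk
        # direction: centroids of oblique sections of a tube still lie on
        # its axis, and matching components by continuity keeps the two
        # branches apart even before their axes are known.
        chains = [[split_comps[0]["centroid"]], [split_comps[1]["centroid"]]]
        alive = [True, True]
        for j in range(1, 5):
            if not any(alive):
                break
            q = np.asarray(q_split) + j * step * d_end
            comps = _section_components(mesh, q, d_end, tm=tm)
            closed = [c for c in comps if c["closed"] and c["perimeter"] > 2 * step]
            claimed = []
            for b in (0, 1):
                if not alive[b]:
                    continue
                pred = chains[b][-1] + step * d_end
                cands = [
                    c
                    for c in closed
                    if np.linalg.norm(c["centroid"] - pred) < 5 * step
                    and not any(c is cc for cc in claimed)
                ]
                if not cands:
                    alive[b] = False
                    continue
                pick = min(cands, key=lambda c: np.linalg.norm(c["centroid"] - pred))
                claimed.append(pick)
                chains[b].append(pick["centroid"])
        # once branch identity is established, follow each branch with the
        # adaptive march (planes orthogonal to the branch's own axis)
        for b in (0, 1):
            ch = [np.asarray(x, float) for x in chains[b]]
            if len(ch) >= 2:
                d_b = ch[-1] - ch[0]
                d_b = d_b / np.linalg.norm(d_b)
                more, _, _ = march(ch[-1], d_b, diag, watch_split=False)
                ch.extend(more[1:])
            chains[b] = ch
        # label branches by proximity of their far end to the labelled openings
        ends = [chains[0][-1], chains[1][-1]]
        d_l = [np.linalg.norm(e - opening_centroids["lpa"]) for e in ends]
        d_r = [np.linalg.norm(e - opening_centroids["rpa"]) for e in ends]
        i_l = 0 if d_l[0] + d_r[1] <= d_l[1] + d_r[0] else 1
        branch_map = {"lpa": list(chains[i_l]), "rpa": list(chains[1 - i_l])}
        # extend each branch to its opening centroid when it stopped nearby
        # (oblique end sections die up to ~r*tan(angle) before the opening)
        for nm in ("lpa", "rpa"):
            pts = branch_map[nm]
            oc = opening_centroids.get(nm)
            if oc is None:
                continue
            r_last = inscribed(pts[-1])
            if np.linalg.norm(pts[-1] - oc) < max(3 * step, r_last + 2 * step):
                pts.append(oc)
        for nm in ("lpa", "rpa"):
            branch_map[nm] = [np.asarray(bif, float)] + branch_map[nm]
    else:
        # degenerate single tube (no bifurcation found): extend the trunk to
        # the far opening (the boundary loop farthest from the inlet), then
        # attach zero-length stub branches
        cents = mesh.loop_centroids()
        far = max(cents, key=lambda c: np.linalg.norm(c - p0))
        r_last = inscribed(trunk_pts[-1])
        if np.linalg.norm(trunk_pts[-1] - far) < 2.5 * r_last + 2 * step:
            trunk_pts.append(far)
        bif = trunk_pts[-1]
        tangent = trunk_pts[-1] - trunk_pts[-2]
        tangent /= np.linalg.norm(tangent)
        stub = [bif, bif + 1e-3 * tangent]
        branch_map = {"lpa": list(stub), "rpa": list(stub)}

    def to_polyline(pts):
        pts = np.asarray(pts)
        rad = locator.query(pts)[1]
        rad = np.maximum(rad, 1e-6)
        return Polyline(pts, rad)

    trunk_all = list(trunk_pts)
    trunk_all[-1] = np.asarray(bif, float)
    trunk = to_polyline(_dedupe(trunk_all))
    lpa = to_polyline(_dedupe([bif] + list(branch_map["lpa"][1:])))
    rpa = to_polyline(_dedupe([bif] + list(branch_map["rpa"][1:])))
    return Centreline(trunk, lpa, rpa, np.asarray(bif, float))


def _dedupe(pts, tol=1e-9):
    out = [np.asarray(pts[0], float)]
    for p in pts[1:]:
        if np.linalg.norm(np.asarray(p) - out[-1]) > tol:
            out.append(np.asarray(p, float))
    if len(out) == 1:
        out.append(out[0] + np.array([0.0, 0.0, 1e-6]))
    return np.asarray(out)


# ----------------------------------------------------------------------
# region-of-interest clipping


def clip_rois(
    mesh: SurfaceMesh,
    centreline: Centreline,
    proximal_arclength: float,
    r_max: float | None = None,
) -> SurfaceMesh:
    """Clip the proximal trunk and branch ends with centreline-orthogonal planes.

    The proximal cut is taken at ``proximal_arclength`` along the trunk;
    each branch is cut at centreline distance from the bifurcation equal to
    the maximum inscribed-sphere radius over the (remaining) proximal trunk.
    Returns a new mesh with relabelled boundary loops; clip planes are
    stored in ``mesh.boundary_labels`` order inlet/lpa/rpa.
    """
    trunk = centreline.trunk
    if not (0.0 <= proximal_arclength <= trunk.length):
        raise ValueError("proximal_arclength outside trunk range")
    if r_max is None:
        mask = trunk.arclength >= proximal_arclength
        r_max = float(trunk.radius[mask].max()) if mask.any() else float(trunk.radius.max())

    planes = {}
    tm = mesh.to_trimesh()
    if proximal_arclength > 0:
        origin = trunk.point_at(proximal_arclength)
        normal = trunk.tangent_at(proximal_arclength)  # keep distal side
        tm = slice_mesh_plane(tm, plane_normal=normal, plane_origin=origin)
        planes["inlet"] = (origin, -normal)
    for name, br in centreline.branches().items():
        if br.length <= r_max:
            warnings.warn(
                f"branch {name} shorter than R_max={r_max:.1f} mm; clipped at branch end"
            )
            continue
        origin = br.point_at(r_max)
        normal = -br.tangent_at(r_max)  # keep proximal side
        tm = slice_mesh_plane(tm, plane_normal=normal, plane_origin=origin)
        planes[name] = (origin, -normal)

    # stitch the cut: slicing leaves duplicated vertices along each cut loop
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    out = SurfaceMesh.from_trimesh(tm)
    # drop stray degenerate faces from slicing
    areas = np.linalg.norm(out.face_normals_area, axis=1)
    if np.any(areas <= 1e-12):
        out = SurfaceMesh(out.vertices, out.faces[areas > 1e-12])
    _relabel_after_clip(out, mesh, planes)
    out.clip_planes = planes
    return out


def _relabel_after_clip(out: SurfaceMesh, original: SurfaceMesh, planes: dict):
    """Label the clipped mesh's loops by nearest original opening or cut plane."""
    cents = out.loop_centroids()
    targets = {}
    for name in ("inlet", "lpa", "rpa"):
        if name in planes:
            targets[name] = planes[name][0]
        else:
            try:
                targets[name] = original.vertices[original.labelled_loop(name)].mean(axis=0)
            except KeyError:
                pass
    labels = {}
    for name, pos in targets.items():
        if len(cents) == 0:
            break
        d = np.linalg.norm(cents - pos, axis=1)
        labels[int(np.argmin(d))] = name
    out.boundary_labels = labels


def export_clip_planes(planes: dict, path) -> None:
    """Write clip planes as CSV rows (label, point, unit normal)."""
    import pandas as pd

    rows = []
    for name, (origin, normal) in planes.items():
        n = np.asarray(normal) / np.linalg.norm(normal)
        rows.append(
            dict(
                label=name,
                px=origin[0], py=origin[1], pz=origin[2],
                nx=n[0], ny=n[1], nz=n[2],
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
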