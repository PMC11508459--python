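"""Mesh I/O, surface area, and isotropic re-meshing.

Re-meshing follows the incremental split/collapse/flip + tangential
smoothing scheme standard for isotropic surface remeshing, with boundary
loops preserved (boundary vertices only move along their loop) and the
result projected back onto the input surface.  The target edge length for
a population is chosen by the surface-area sensitivity criterion: the
largest candidate for which remeshing the smallest-area subject changes
its area by less than 0.5%.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import trimesh

from .geometry import SurfaceMesh, SurfaceLocator

SUPPORTED_FORMATS = ("stl", "ply", "obj")


def read_mesh(path, format: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface (STL, PLY or OBJ).

    STL stores no connectivity, so vertices are merged at 1e-6 mm.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        raise ValueError("legacy VTK surface format is not supported; use PLY")
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"parse error: {path} is empty")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as e:  # normalise loader errors
        raise ValueError(f"parse error in {path}: {e}") from e
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"parse error: {path} contains no triangles")
    if fmt == "stl":
        tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    return SurfaceMesh.from_trimesh(tm)


def write_mesh(mesh: SurfaceMesh, path, format: str | None = None) -> None:
    """Write a surface as binary STL or ascii PLY/OBJ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        tm.export(str(path), file_type=fmt)


def surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area in mm² (sum of triangle areas)."""
    return mesh.area


# ----------------------------------------------------------------------
# incremental isotropic remeshing


class _EditableMesh:
    """Light half-edge-free editable triangle mesh for remeshing."""

    def __init__(self, mesh: SurfaceMesh):
        self.v = [p.copy() for p in mesh.vertices]
        self.faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
        self.next_fid = len(mesh.faces)
        self.v2f = {}
        for fid, f in self.faces.items():
            for vid in f:
                self.v2f.setdefault(int(vid), set()).add(fid)

    # -- queries ---------------------------------------------------------
    def edge_faces(self, a, b):
        return [fid for fid in self.v2f.get(a, ()) if b in self.faces[fid]]

    def edges(self):
        seen = set()
        for f in self.faces.values():
            for i in range(3):
                a, b = f[i], f[(i + 1) % 3]
                key = (min(a, b), max(a, b))
                if key not in seen:
                    seen.add(key)
                    yield key

    def is_boundary_edge(self, a, b):
        return len(self.edge_faces(a, b)) == 1

    def neighbors(self, a):
        out = set()
        for fid in self.v2f.get(a, ()):
            out.update(self.faces[fid])
        out.discard(a)
        return out

    # -- edits -----------------------------------------------------------
    def add_face(self, f):
        fid = self.next_fid
        self.next_fid += 1
        self.faces[fid] = tuple(int(x) for x in f)
        for vid in self.faces[fid]:
            self.v2f.setdefault(vid, set()).add(fid)
        return fid

    def remove_face(self, fid):
        for vid in self.faces[fid]:
            s = self.v2f.get(vid)
            if s is not None:
                s.discard(fid)
        del self.faces[fid]

    def split_edge(self, a, b):
        mid = 0.5 * (self.v[a] + self.v[b])
        self.v.append(mid)
        m = len(self.v) - 1
        for fid in list(self.edge_faces(a, b)):
            f = self.faces[fid]
            c = [x for x in f if x not in (a, b)][0]
            # preserve orientation
            i_a = f.index(a)
            if f[(i_a + 1) % 3] == b:
                self.remove_face(fid)
                self.add_face((a, m, c))
                self.add_face((m, b, c))
            else:
                self.remove_face(fid)
                self.add_face((b, m, c))
                self.add_face((m, a, c))
        return m

    def collapse_edge(self, a, b, target):
        """Collapse b into a placed at ``target``. Returns False if illegal."""
        # link condition: shared neighbours must be exactly the edge's
        # opposite vertices, otherwise collapsing pinches the surface
        shared = self.neighbors(a) & self.neighbors(b)
        opposite = set()
        for fid in self.edge_faces(a, b):
            opposite.update(x for x in self.faces[fid] if x not in (a, b))
        if shared != opposite:
            return False
        for fid in list(self.edge_faces(a, b)):
            self.remove_face(fid)
        for fid in list(self.v2f.get(b, set())):
            f = self.faces[fid]
            newf = tuple(a if x == b else x for x in f)
            if len(set(newf)) < 3:
                self.remove_face(fid)
                continue
            self.remove_face(fid)
            self.add_face(newf)
        self.v2f.pop(b, None)
        self.v[a] = np.asarray(target, float)
        return True

    def flip_edge(self, a, b):
        fids = self.edge_faces(a, b)
        if len(fids) != 2:
            return False
        f1, f2 = (self.faces[fid] for fid in fids)
        c = [x for x in f1 if x not in (a, b)][0]
        d = [x for x in f2 if x not in (a, b)][0]
        if c == d or d in self.neighbors(c):
            return False
        # orientation: keep winding consistent with f1
        i_a = f1.index(a)
        if f1[(i_a + 1) % 3] != b:
            a, b = b, a
        for fid in fids:
            self.remove_face(fid)
        self.add_face((a, d, c))
        self.add_face((d, b, c))
        return True

    def to_surface(self) -> SurfaceMesh:
        used = sorted({v for f in self.faces.values() for v in f})
        remap = {old: i for i, old in enumerate(used)}
        verts = np.asarray([self.v[i] for i in used])
        faces = np.asarray(
            [[remap[x] for x in f] for f in self.faces.values()], dtype=np.int64
        )
        return SurfaceMesh(verts, faces)


def remesh(
    mesh: SurfaceMesh, target_edge_length: float, n_sweeps: int = 4
) -> SurfaceMesh:
    """Isotropic remeshing to a target edge length (mm).

    Runs ``n_sweeps`` sweeps of edge split / collapse / flip and tangential
    smoothing with projection back to the input surface.  Boundary loops
    are preserved together with their labels; the relative surface-area
    change is stored on the result as ``sa_change``.
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    if target_edge_length > mesh.bounding_box_diagonal():
        raise ValueError("target edge length exceeds the bounding-box diagonal")

    sa_before = mesh.area
    n_loops_before = len(mesh.boundary_loops())
    locator = SurfaceLocator(mesh)
    em = _EditableMesh(mesh)
    high = 4.0 / 3.0 * target_edge_length
    low = 0.8 * target_edge_length
    feature_cos = np.cos(np.radians(45.0))

    def boundary_vertices():
        bnd = set()
        for a, b in em.edges():
            if em.is_boundary_edge(a, b):
                bnd.add(a)
                bnd.add(b)
        return bnd

    def face_normal(fid):
        f = em.faces[fid]
        n = np.cross(em.v[f[1]] - em.v[f[0]], em.v[f[2]] - em.v[f[0]])
        nn = np.linalg.norm(n)
        return n / nn if nn > 0 else n

    def feature_vertices():
        """Vertices on sharp ridges/grooves (e.g. the bifurcation saddle):
        the cone of incident face normals opens wider than 45 degrees."""
        frozen = set()
        for vid, fids in em.v2f.items():
            normals = [face_normal(fid) for fid in fids]
            for i in range(len(normals)):
                for j in range(i + 1, len(normals)):
                    if normals[i] @ normals[j] < feature_cos:
                        frozen.add(vid)
                        break
                else:
                    continue
                break
        return frozen

    for sweep in range(n_sweeps):
        # 1. split long edges
        for a, b in list(em.edges()):
            if a not in em.v2f or b not in em.v2f:
                continue
            if not em.edge_faces(a, b):
                continue
            if np.linalg.norm(em.v[a] - em.v[b]) > high:
                em.split_edge(a, b)
        # 2. collapse short edges (never across a feature ridge)
        bnd = boundary_vertices()
        frozen = feature_vertices()
        for a, b in list(em.edges()):
            if a not in em.v2f or b not in em.v2f:
                continue
            ef = em.edge_faces(a, b)
            if not ef:
                continue
            if a in frozen or b in frozen:
                continue
            d = np.linalg.norm(em.v[a] - em.v[b])
            if d >= low:
                continue
            a_b, b_b = a in bnd, b in bnd
            if a_b and b_b:
                if len(ef) != 1:
                    continue  # interior edge between boundary vertices: pinch risk
                cand_targets = [0.5 * (em.v[a] + em.v[b])]
            elif a_b:
                cand_targets = [em.v[a]]
            elif b_b:
                a, b = b, a
                cand_targets = [em.v[a]]
            else:
                cand_targets = [0.5 * (em.v[a] + em.v[b]), em.v[a].copy(), em.v[b].copy()]
            # area-preserving target choice: collapsing flattens the tent the
            # removed vertex made over the curved surface, so pick whichever
            # candidate keeps the joint one-ring area best, and skip the
            # collapse entirely if none stays within 1%
            ring_fids = set(em.v2f[a]) | set(em.v2f[b])
            before = 0.0
            for fid in ring_fids:
                p = [em.v[x] for x in em.faces[fid]]
                before += 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            collapse_fids = set(ef)
            best = None
            for tgt in cand_targets:
                after = 0.0
                for fid in ring_fids - collapse_fids:
                    p = [
                        tgt if x in (a, b) else em.v[x] for x in em.faces[fid]
                    ]
                    after += 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
                rel = abs(after - before) / before if before > 0 else 0.0
                if best is None or rel < best[0]:
                    best = (rel, tgt)
            # the admissible chordal loss grows with the square of the edge
            # length being created (sag ~ e^2 / 8r), so coarser targets get
            # a proportionally looser per-collapse budget
            collapse_budget = min(0.05, 0.002 * (target_edge_length / 2.0) ** 2)
            if best is None or best[0] > collapse_budget:
                continue
            target = best[1]
            # forbid creating overlong edges
            if any(
                np.linalg.norm(em.v[n] - target) > 1.2 * high
                for n in em.neighbors(b)
                if n != a
            ):
                continue
            if em.collapse_edge(a, b, target):
                bnd = bnd if not (a_b and b_b) else boundary_vertices()
        # 3. valence-equalising flips (interior edges only)
        bnd = boundary_vertices()
        val = {vid: len(em.neighbors(vid)) for vid in em.v2f}

        def opt_val(vid):
            return 4 if vid in bnd else 6

        for a, b in list(em.edges()):
            if a not in em.v2f or b not in em.v2f:
                continue
            fids = em.edge_faces(a, b)
            if len(fids) != 2:
                continue
            # never flip across a sharp dihedral (feature edge)
            if face_normal(fids[0]) @ face_normal(fids[1]) < feature_cos:
                continue
            cs = [x for fid in fids for x in em.faces[fid] if x not in (a, b)]
            if len(cs) != 2:
                continue
            c, d = cs
            dev_before = sum(
                abs(val.get(x, 0) - opt_val(x)) for x in (a, b, c, d)
            )
            val_after = {a: val[a] - 1, b: val[b] - 1, c: val[c] + 1, d: val[d] + 1}
            dev_after = sum(abs(val_after[x] - opt_val(x)) for x in (a, b, c, d))
            if dev_after >= dev_before:
                continue
            # flips must be (nearly) area-neutral: on a curved surface
            # swapping the diagonal of a non-planar quad changes area
            pa, pb, pc, pd = em.v[a], em.v[b], em.v[c], em.v[d]
            area_before = 0.5 * (
                np.linalg.norm(np.cross(pb - pa, pc - pa))
                + np.linalg.norm(np.cross(pb - pa, pd - pa))
            )
            area_after = 0.5 * (
                np.linalg.norm(np.cross(pd - pc, pa - pc))
                + np.linalg.norm(np.cross(pd - pc, pb - pc))
            )
            if area_before > 0 and abs(area_after - area_before) / area_before > 0.005:
                continue
            if em.flip_edge(a, b):
                for x in (a, b, c, d):
                    val[x] = val_after[x]
        # 4. tangential smoothing + projection to the original surface;
        #    feature vertices (saddle groove, ridges) stay put
        bnd = boundary_vertices()
        frozen = feature_vertices() | bnd
        ids = [vid for vid in em.v2f if vid not in frozen and em.v2f[vid]]
        if ids:
            new_pos = {}
            for vid in ids:
                nbrs = em.neighbors(vid)
                if not nbrs:
                    continue
                cen = np.mean([em.v[n] for n in nbrs], axis=0)
                new_pos[vid] = em.v[vid] + 0.5 * (cen - em.v[vid])
            keys = list(new_pos)
            pts = np.asarray([new_pos[vid] for vid in keys])
            proj, dist, fidx = locator.query(pts)
            src_n = locator.query(np.asarray([em.v[vid] for vid in keys]))[2]
            fn = mesh.face_normals_area
            fn = fn / np.linalg.norm(fn, axis=1, keepdims=True)

            def ring_area(vid, pos):
                total = 0.0
                for fid in em.v2f[vid]:
                    p = [pos if x == vid else em.v[x] for x in em.faces[fid]]
                    total += 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
                return total

            for i, vid in enumerate(keys):
                # reject moves that land on a different sheet of the surface
                if fn[src_n[i]] @ fn[fidx[i]] <= 0.5:
                    continue
                # reject moves that change local area (corner-cutting at
                # concave features such as the bifurcation groove)
                before = ring_area(vid, em.v[vid])
                after = ring_area(vid, proj[i])
                if before > 0 and abs(after - before) / before > 0.0005:
                    continue
                em.v[vid] = proj[i]

    # cleanup: degenerate faces are removed by collapsing their shortest
    # edge (deleting them outright would tear holes in the surface)
    for _ in range(3):
        bad = []
        for fid, f in list(em.faces.items()):
            if fid not in em.faces:
                continue
            p = [em.v[x] for x in f]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            if area <= 1e-10:
                bad.append(fid)
        if not bad:
            break
        for fid in bad:
            if fid not in em.faces:
                continue
            f = em.faces[fid]
            pairs = [(f[0], f[1]), (f[1], f[2]), (f[2], f[0])]
            a, b = min(pairs, key=lambda e: np.linalg.norm(em.v[e[0]] - em.v[e[1]]))
            em.collapse_edge(a, b, 0.5 * (em.v[a] + em.v[b]))

    out = em.to_surface()
    out.relabel_loops_from(mesh)
    if len(out.boundary_loops()) != n_loops_before:
        warnings.warn("remeshing changed the number of boundary loops")
    out.sa_change = abs(out.area - sa_before) / sa_before
    return out


def median_edge_length(mesh: SurfaceMesh) -> float:
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    return float(
        np.median(np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1))
    )


def select_target_edge_length(
    population: list[SurfaceMesh], candidates: list[float], threshold: float = 0.005
) -> float:
    """Pick the re-meshing edge length by the area-sensitivity criterion.

    The subject with the smallest surface area bounds the admissible
    coarseness: the largest candidate changing its area by less than
    ``threshold`` (0.5% by default) is selected.  Falls back to the
    smallest candidate with a warning when none pass.
    """
    if not population:
        raise ValueError("population is empty")
    if not candidates:
        raise ValueError("candidates is empty")
    candidates = sorted(candidates)
    smallest = min(population, key=surface_area)
    med0 = median_edge_length(smallest)
    chosen = None
    for cand in candidates:
        try:
            rm = remesh(smallest, cand)
        except ValueError:
            continue
        # a candidate only counts when the remesh actually reached it
        # (coarse targets the area guards refuse to realise do not pass)
        med = median_edge_length(rm)
        reached = abs(med - cand) <= 0.3 * cand
        if rm.sa_change < threshold and reached:
            chosen = cand
    if chosen is None:
        warnings.warn(
            "no candidate satisfied the surface-area criterion; "
            "falling back to the smallest candidate"
        )
        chosen = candidates[0]
    return chosen
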