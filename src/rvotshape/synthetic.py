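"""Synthetic bifurcating-vessel cohort generator.

Patient surfaces of the kind analysed here (post-surgical right
ventricular outflow tracts segmented from CMR) are not publicly
shareable, so the pipeline is driven by a parametric stand-in: open
Y-shaped tubular surfaces swept along a curved trunk spline with
taper, a mid-trunk bulge, frontal/sagittal curvature, an elliptical
inlet and two branch tubes.  Because every surface comes with its
generative spline, radius profile and landmarks, downstream stages
(centreline extraction, registration, atlas estimation, PCA) can be
validated against ground truth.

The module also packages the study's screening log and cohort
characteristic tables as deterministic fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh
from .centerline import Centreline, Polyline


# ----------------------------------------------------------------------
# shape parameters


@dataclass
class ShapeParams:
    """Generative factors of one synthetic vessel.

    Lengths and radii are in mm before the global ``size_scale`` is
    applied; curvatures are signed, in 1/mm.  ``size_scale`` produces a
    geometrically similar shape (curvatures scale as 1/size_scale), so
    surface area scales exactly with its square.
    """

    size_scale: float = 1.0
    trunk_length: float = 55.0
    taper: float = 0.25
    bulge_amp: float = 0.15
    bulge_pos: float = 0.5
    curv_frontal: float = 0.004
    curv_sagittal: float = 0.004
    r_inlet: float = 14.0
    r_lpa: float = 7.0
    r_rpa: float = 7.0
    branch_angle_lpa: float = 40.0
    branch_angle_rpa: float = 40.0
    inlet_ellipticity: float = 1.15
    inlet_rotation: float = 0.0
    branch_length_lpa: float | None = None
    branch_length_rpa: float | None = None
    bulge_width: float = 0.02  # squared fraction units; bulge spans ~30% of trunk

    def validate(self) -> None:
        for name in ("r_inlet", "r_lpa", "r_rpa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trunk_length <= 0:
            raise ValueError("trunk_length must be positive")
        if not (0.0 <= self.bulge_pos <= 1.0):
            raise ValueError("bulge_pos must lie in [0, 1]")
        if self.inlet_ellipticity < 1.0:
            raise ValueError("inlet_ellipticity must be >= 1")
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must lie in [0, 1)")

    def branch_lengths(self) -> tuple[float, float]:
        bl = self.branch_length_lpa
        br = self.branch_length_rpa
        if bl is None:
            bl = 0.32 * self.trunk_length
        if br is None:
            br = 0.32 * self.trunk_length
        return bl, br

    def radius_profile(self, s_frac: np.ndarray) -> np.ndarray:
        """Trunk radius (pre-scale, mm) at arc-length fraction ``s_frac``."""
        s_frac = np.asarray(s_frac, dtype=float)
        bulge = self.bulge_amp * np.exp(
            -((s_frac - self.bulge_pos) ** 2) / self.bulge_width
        )
        return self.r_inlet * (1.0 - self.taper * s_frac) * (1.0 + bulge)


@dataclass
class CohortRecord:
    subject_id: str
    sex: str
    age_years: float
    diagnosis: str
    rvot_type: str
    dysfunction: str
    exclusion_flag: str = "none"

    SEXES = ("F", "M")
    DIAGNOSES = ("ToF", "ToF+PA", "Other")
    RVOT_TYPES = ("TAP", "Conduit", "RVOT-Patch", "Other")
    DYSFUNCTIONS = ("Regurgitant", "Mixed", "Stenotic")
    EXCLUSIONS = (
        "none",
        "pa_stent",
        "interrupted_lpa",
        "poor_image",
        "no_surgical_data",
        "recent_pvr",
    )

    def __post_init__(self):
        if self.sex not in self.SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.diagnosis not in self.DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.rvot_type not in self.RVOT_TYPES:
            raise ValueError(f"unknown rvot_type {self.rvot_type!r}")
        if self.dysfunction not in self.DYSFUNCTIONS:
            raise ValueError(f"unknown dysfunction {self.dysfunction!r}")
        if self.exclusion_flag not in self.EXCLUSIONS:
            raise ValueError(f"unknown exclusion_flag {self.exclusion_flag!r}")
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")


# ----------------------------------------------------------------------
# surface generation


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _trunk_spline(params: ShapeParams, n_fine: int = 600):
    """Integrate the trunk centreline with exact unit-speed tangents.

    Returns (points (n,3), tangents (n,3), frames u1/u2 parallel-transported,
    arclength (n,)).  Arc length is exact by construction.
    """
    L = params.trunk_length * params.size_scale
    kf = params.curv_frontal / params.size_scale
    ks = params.curv_sagittal / params.size_scale
    ds = L / (n_fine - 1)
    pts = np.zeros((n_fine, 3))
    tans = np.zeros((n_fine, 3))
    u1s = np.zeros((n_fine, 3))
    t = np.array([0.0, 0.0, 1.0])
    u1 = np.array([1.0, 0.0, 0.0])
    # frontal curvature bends in the x-z plane (about +y), sagittal in y-z (about -x)
    tans[0] = t
    u1s[0] = u1
    for i in range(1, n_fine):
        R = _rotation([0.0, 1.0, 0.0], kf * ds) @ _rotation([1.0, 0.0, 0.0], -ks * ds)
        t_new = R @ t
        pts[i] = pts[i - 1] + 0.5 * ds * (t + t_new)  # midpoint rule, |step| ~ ds
        # parallel transport u1 to the new tangent
        axis = np.cross(t, t_new)
        na = np.linalg.norm(axis)
        if na > 1e-14:
            ang = math.atan2(na, float(t @ t_new))
            u1 = _rotation(axis, ang) @ u1
        t = t_new
        tans[i] = t
        u1s[i] = u1
    # exact arclength: the tangent is always unit so s_i = i*ds up to the
    # midpoint-rule chord; rescale positions so chordal length matches s
    s = np.arange(n_fine) * ds
    return pts, tans, u1s, s


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def generate_shape(
    params: ShapeParams,
    axial_samples: int = 48,
    circumferential_samples: int = 32,
    seed: int = 0,
    noise_mm: float = 0.0,
    suppress_branches: bool = False,
):
    """Generate one synthetic Y-vessel surface with ground truth.

    Returns ``(mesh, centreline, landmarks)`` where the centreline is the
    generative spline with analytic arc length and the landmarks are the
    three open ends plus the bifurcation point.

    Raises ``ValueError`` when the requested curvature would make the tube
    self-intersect (radius of curvature smaller than the tube radius).
    """
    from .measurements import LandmarkSet

    params.validate()
    if axial_samples < 8 or circumferential_samples < 8:
        raise ValueError("sample counts must be >= 8")
    C = int(circumferential_samples)
    C -= C % 4  # split of the end ring needs C divisible by 4
    C = max(C, 8)
    A = int(axial_samples)

    scale = params.size_scale
    L = params.trunk_length * scale
    # self-intersection guard: bend radius must exceed the widest tube radius
    kappa = math.hypot(params.curv_frontal, params.curv_sagittal) / scale
    r_max = float(params.radius_profile(np.linspace(0, 1, 200)).max()) * scale
    if kappa > 0 and r_max >= 0.9 / kappa:
        worst = (
            "curv_frontal"
            if abs(params.curv_frontal) >= abs(params.curv_sagittal)
            else "curv_sagittal"
        )
        raise ValueError(
            f"self-intersecting surface: {worst} too large for tube radius "
            f"(bend radius {1/kappa:.1f} mm <= max tube radius {r_max:.1f} mm)"
        )

    pts_f, tans_f, u1_f, s_f = _trunk_spline(params)
    frac = np.linspace(0.0, 1.0, A + 1)
    idx = np.round(frac * (len(s_f) - 1)).astype(int)
    ring_c = pts_f[idx]
    ring_t = tans_f[idx]
    ring_u1 = u1_f[idx]
    ring_u2 = np.cross(ring_t, ring_u1)
    radii = params.radius_profile(frac) * scale

    theta = 2 * np.pi * np.arange(C) / C
    rot0 = math.radians(params.inlet_rotation)
    ell = 1.0 + (params.inlet_ellipticity - 1.0) * (1.0 - frac)  # circular at the end

    verts = []
    ring_index = np.zeros((A + 1, C), dtype=int)
    for i in range(A + 1):
        a = radii[i] * math.sqrt(ell[i])
        b = radii[i] / math.sqrt(ell[i])
        cosr, sinr = math.cos(rot0), math.sin(rot0)
        x_loc = a * np.cos(theta)
        y_loc = b * np.sin(theta)
        xr = cosr * x_loc - sinr * y_loc
        yr = sinr * x_loc + cosr * y_loc
        ring = ring_c[i] + np.outer(xr, ring_u1[i]) + np.outer(yr, ring_u2[i])
        ring_index[i] = np.arange(len(verts), len(verts) + C)
        verts.extend(ring)
    faces = []
    for i in range(A):
        for k in range(C):
            k2 = (k + 1) % C
            a0, a1 = ring_index[i, k], ring_index[i, k2]
            b0, b1 = ring_index[i + 1, k], ring_index[i + 1, k2]
            faces.append([a0, b0, b1])
            faces.append([a0, b1, a1])

    O = ring_c[-1]
    t_end = ring_t[-1]
    u1e, u2e = ring_u1[-1], ring_u2[-1]
    end_ring = ring_index[-1]

    bl_len, br_len = params.branch_lengths()
    bl_len *= scale
    br_len *= scale
    r_lpa = params.r_lpa * scale
    r_rpa = params.r_rpa * scale

    branch_end_centers = {}
    if not suppress_branches:
        q = C // 4
        # shared seam: straight chord between the two saddle vertices through O
        p_top = np.asarray(verts[end_ring[q]])
        p_bot = np.asarray(verts[end_ring[3 * q]])
        n_seam = C // 2 - 1
        tvals = np.linspace(0.0, 1.0, n_seam + 2)[1:-1]
        seam_idx = []
        for tv in tvals:
            seam_idx.append(len(verts))
            verts.append((1 - tv) * p_top + tv * p_bot)
        seam_idx = np.array(seam_idx, dtype=int)

        def branch_base(side):
            # ordered closed base loop (indices into verts)
            if side == "lpa":  # +u1 half
                ring_part = [end_ring[(3 * q + j) % C] for j in range(0, C // 2 + 1)]
                loop = ring_part + list(seam_idx[::-1])
            else:  # -u1 half
                ring_part = [end_ring[q + j] for j in range(0, C // 2 + 1)]
                loop = ring_part + list(seam_idx)
            return np.array(loop, dtype=int)

        for side, sign, angle_deg, r_b, blen in (
            ("lpa", +1.0, params.branch_angle_lpa, r_lpa, bl_len),
            ("rpa", -1.0, params.branch_angle_rpa, r_rpa, br_len),
        ):
            base = branch_base(side)
            base_pts = np.asarray([verts[j] for j in base])
            d_b = _rotation(u2e, sign * math.radians(angle_deg)) @ t_end
            # frame orthogonal to the branch axis
            w1 = u1e - (u1e @ d_b) * d_b
            w1 /= np.linalg.norm(w1)
            w2 = np.cross(d_b, w1)
            base_c = base_pts.mean(axis=0)
            rel = base_pts - base_c
            ang = np.arctan2(rel @ w2, rel @ w1)
            n_rings = max(A // 3, 6)
            prev = base
            for j in range(1, n_rings + 1):
                f = j / n_rings
                w = _smoothstep(1.5 * f)
                ctr = base_c + f * blen * d_b
                circ = ctr + r_b * (
                    np.outer(np.cos(ang), w1) + np.outer(np.sin(ang), w2)
                )
                slid = base_pts + f * blen * d_b
                ring = (1 - w) * slid + w * circ
                ring_ids = np.arange(len(verts), len(verts) + len(base))
                verts.extend(ring)
                for k in range(len(base)):
                    k2 = (k + 1) % len(base)
                    a0, a1 = prev[k], prev[k2]
                    b0, b1 = ring_ids[k], ring_ids[k2]
                    if side == "lpa":
                        faces.append([a0, b0, b1])
                        faces.append([a0, b1, a1])
                    else:
                        faces.append([a0, b0, b1])
                        faces.append([a0, b1, a1])
                prev = ring_ids
            branch_end_centers[side] = base_c + blen * d_b

    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if noise_mm > 0:
        rng = np.random.default_rng(seed)
        # displace along vertex normals, leaving boundary rings untouched
        tmp = SurfaceMesh(verts, faces)
        tm = tmp.to_trimesh()
        normals = np.asarray(tm.vertex_normals)
        disp = rng.normal(0.0, noise_mm, size=len(verts))
        bnd = tmp.boundary_vertex_set()
        disp[list(bnd)] = 0.0
        verts = verts + normals * disp[:, None]

    mesh = SurfaceMesh(verts, faces)
    # drop exactly-degenerate faces (possible when a branch angle is 0)
    areas = np.linalg.norm(mesh.face_normals_area, axis=1)
    if np.any(areas <= 1e-12):
        mesh = SurfaceMesh(verts, faces[areas > 1e-12])

    # ground-truth centreline + landmarks
    prof = params.radius_profile(frac) * scale
    trunk = Polyline(ring_c, np.maximum(prof, 1e-6))
    if suppress_branches:
        stub = np.vstack([O, O + 1e-3 * t_end])
        lpa = Polyline(stub, [prof[-1], prof[-1]])
        rpa = Polyline(stub.copy(), [prof[-1], prof[-1]])
        lm_lpa = O.copy()
        lm_rpa = O.copy()
    else:
        n_b = 12
        for side, r_b in (("lpa", r_lpa), ("rpa", r_rpa)):
            endc = branch_end_centers[side]
            tt = np.linspace(0, 1, n_b)[:, None]
            pts_b = O * (1 - tt) + endc * tt
            pl = Polyline(pts_b, np.full(n_b, r_b))
            if side == "lpa":
                lpa = pl
                lm_lpa = endc
            else:
                rpa = pl
                lm_rpa = endc
    centreline = Centreline(trunk, lpa, rpa, O.copy())
    landmarks = LandmarkSet(
        proximal=ring_c[0].copy(), lpa_end=lm_lpa, rpa_end=lm_rpa, bifurcation=O.copy()
    )

    # label boundary loops by nearest landmark
    loop_cents = mesh.loop_centroids()
    targets = {"inlet": landmarks.proximal}
    if not suppress_branches:
        targets["lpa"] = landmarks.lpa_end
        targets["rpa"] = landmarks.rpa_end
    labels = {}
    for name, pos in targets.items():
        d = np.linalg.norm(loop_cents - pos, axis=1)
        labels[int(np.argmin(d))] = name
    mesh.boundary_labels = labels
    mesh.validate()
    return mesh, centreline, landmarks


# ----------------------------------------------------------------------
# population sampling

#: per-parameter base mean and shared SD of the sampling distribution
PARAM_BASE = dict(
    size_scale=1.0,
    trunk_length=55.0,
    taper=0.25,
    bulge_amp=0.15,
    bulge_pos=0.5,
    curv_frontal=0.004,
    curv_sagittal=0.004,
    r_inlet=14.0,
    r_lpa=7.0,
    r_rpa=7.0,
    branch_angle_lpa=40.0,
    branch_angle_rpa=40.0,
    inlet_ellipticity=1.15,
    inlet_rotation=0.0,
)

PARAM_SD = dict(
    size_scale=0.16,
    trunk_length=7.0,
    taper=0.08,
    bulge_amp=0.10,
    bulge_pos=0.12,
    curv_frontal=0.0025,
    curv_sagittal=0.0025,
    r_inlet=1.8,
    r_lpa=0.9,
    r_rpa=0.9,
    branch_angle_lpa=7.0,
    branch_angle_rpa=7.0,
    inlet_ellipticity=0.08,
    inlet_rotation=10.0,
)

# validity bounds used to clip extreme draws
PARAM_BOUNDS = dict(
    size_scale=(0.55, 1.6),
    trunk_length=(35.0, 90.0),
    taper=(0.0, 0.55),
    bulge_amp=(-0.15, 0.55),
    bulge_pos=(0.05, 0.95),
    curv_frontal=(-0.012, 0.012),
    curv_sagittal=(-0.012, 0.012),
    r_inlet=(8.0, 22.0),
    r_lpa=(4.0, 12.0),
    r_rpa=(4.0, 12.0),
    branch_angle_lpa=(20.0, 62.0),
    branch_angle_rpa=(20.0, 62.0),
    inlet_ellipticity=(1.0, 1.5),
    inlet_rotation=(-45.0, 45.0),
)

#: subgroup mean shifts (in ShapeParams units): transannular-patch repairs
#: are larger, more tapered and straighter; conduits longer and more slender
DEFAULT_EFFECTS = {
    "rvot_type": {
        "TAP": dict(size_scale=0.10, taper=0.07, curv_sagittal=-0.0012),
        "Conduit": dict(
            trunk_length=9.0, r_inlet=-2.0, size_scale=-0.06, curv_sagittal=0.0018
        ),
    }
}

#: marginal subgroup proportions of the 81-subject reference cohort
COHORT_PROPORTIONS = {
    "sex": {"F": 40 / 81, "M": 41 / 81},
    "diagnosis": {"ToF": 59 / 81, "ToF+PA": 13 / 81, "Other": 9 / 81},
    "rvot_type": {
        "TAP": 50 / 81,
        "Conduit": 19 / 81,
        "RVOT-Patch": 8 / 81,
        "Other": 4 / 81,
    },
    "dysfunction": {"Regurgitant": 61 / 81, "Mixed": 17 / 81, "Stenotic": 3 / 81},
}

# log-normal age model: median 14.5 y, interquartile range 6.13 y
AGE_MU = math.log(14.5)
AGE_SIGMA = math.asinh(6.13 / (2 * 14.5)) / 0.6744897501960817


def default_effect_config() -> dict:
    return dict(
        base=dict(PARAM_BASE),
        sd=dict(PARAM_SD),
        effects={k: {g: dict(v) for g, v in d.items()} for k, d in DEFAULT_EFFECTS.items()},
        proportions={k: dict(v) for k, v in COHORT_PROPORTIONS.items()},
    )


def sample_population(n: int, effect_config: dict | None = None, seed: int = 0):
    """Draw ``n`` (ShapeParams, CohortRecord) pairs.

    Shape coefficients are independent normals per parameter, with
    subgroup-linked mean shifts from ``effect_config['effects']``; subgroup
    labels are drawn with the configured proportions.  Bit-reproducible
    under a fixed seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    cfg = effect_config or default_effect_config()
    base = {**PARAM_BASE, **cfg.get("base", {})}
    sd = {**PARAM_SD, **cfg.get("sd", {})}
    for k, v in sd.items():
        if v <= 0:
            raise ValueError(f"standard deviation for {k} must be positive")
    effects = cfg.get("effects", {})
    props = cfg.get("proportions", COHORT_PROPORTIONS)

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        labels = {}
        for cat in ("sex", "diagnosis", "rvot_type", "dysfunction"):
            names = list(props[cat])
            p = np.array([props[cat][nm] for nm in names], dtype=float)
            p /= p.sum()
            labels[cat] = str(rng.choice(names, p=p))
        age = float(np.exp(rng.normal(AGE_MU, AGE_SIGMA)))
        record = CohortRecord(
            subject_id=f"S{i+1:03d}",
            sex=labels["sex"],
            age_years=age,
            diagnosis=labels["diagnosis"],
            rvot_type=labels["rvot_type"],
            dysfunction=labels["dysfunction"],
        )
        values = {}
        for name in PARAM_BASE:
            mu = base[name]
            for cat, groups in effects.items():
                shift = groups.get(labels.get(cat), {})
                mu = mu + shift.get(name, 0.0)
            v = rng.normal(mu, sd[name])
            lo, hi = PARAM_BOUNDS[name]
            values[name] = float(np.clip(v, lo, hi))
        out.append((ShapeParams(**values), record))
    return out


def population_to_frame(pop) -> pd.DataFrame:
    """Tidy table of parameters + metadata, one row per subject."""
    rows = []
    for params, rec in pop:
        row = {**asdict(rec)}
        for k, v in asdict(params).items():
            if k in PARAM_BASE:
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# cohort fixtures (screening log and characteristic tables)

# Table 2 cross-tabs: per RVOT type, diagnosis counts and dysfunction counts
_TABLE2_DIAGNOSIS = {
    "TAP": {"ToF": 46, "ToF+PA": 3, "Other": 1},
    "Conduit": {"ToF": 6, "ToF+PA": 7, "Other": 6},
    "RVOT-Patch": {"ToF": 3, "ToF+PA": 3, "Other": 2},
    "Other": {"ToF": 4, "ToF+PA": 0, "Other": 0},
}
_TABLE2_DYSFUNCTION = {
    "TAP": {"Regurgitant": 43, "Mixed": 7, "Stenotic": 0},
    "Conduit": {"Regurgitant": 7, "Mixed": 9, "Stenotic": 3},
    "RVOT-Patch": {"Regurgitant": 8, "Mixed": 0, "Stenotic": 0},
    "Other": {"Regurgitant": 3, "Mixed": 1, "Stenotic": 0},
}
_EXCLUSION_COUNTS = {
    "pa_stent": 5,
    "interrupted_lpa": 2,
    "poor_image": 6,
    "no_surgical_data": 5,
    "recent_pvr": 1,
}


def _joint_allocation(diag_counts: dict, dysf_counts: dict):
    """Greedy north-west-corner fill of the diagnosis x dysfunction table.

    The joint distribution within an RVOT type is under-determined by the
    published marginals; filling greedily in the fixed label order makes
    the allocation deterministic while matching both marginals exactly.
    """
    diags = list(CohortRecord.DIAGNOSES)
    dysfs = list(CohortRecord.DYSFUNCTIONS)
    remaining_d = {k: diag_counts.get(k, 0) for k in diags}
    remaining_y = {k: dysf_counts.get(k, 0) for k in dysfs}
    cells = []
    for dg in diags:
        for dy in dysfs:
            c = min(remaining_d[dg], remaining_y[dy])
            if c > 0:
                cells.append((dg, dy, c))
                remaining_d[dg] -= c
                remaining_y[dy] -= c
    return cells


def build_cohort_table() -> pd.DataFrame:
    """Deterministic 81-subject cohort table matching the published
    characteristic tables exactly (sex, diagnosis, repair type,
    dysfunction marginals and both repair-type cross-tabs)."""
    from scipy.stats import lognorm

    rows = []
    for rtype in CohortRecord.RVOT_TYPES:
        for dg, dy, c in _joint_allocation(
            _TABLE2_DIAGNOSIS[rtype], _TABLE2_DYSFUNCTION[rtype]
        ):
            for _ in range(c):
                rows.append(dict(diagnosis=dg, rvot_type=rtype, dysfunction=dy))
    n = len(rows)
    assert n == 81
    # deterministic sex assignment: alternate starting with M -> 41 M / 40 F
    sexes = ["M" if i % 2 == 0 else "F" for i in range(n)]
    # deterministic ages: log-normal quantiles (median 14.5 y, IQR 6.13 y)
    q = (np.arange(n) + 0.5) / n
    ages = lognorm.ppf(q, s=AGE_SIGMA, scale=math.exp(AGE_MU))
    # interleave age quantiles across the type-ordered rows so no subgroup
    # hoards the extremes: bit-reversal-style permutation
    order = np.argsort(np.argsort((np.arange(n) * 37) % n))
    records = []
    for i, row in enumerate(rows):
        records.append(
            asdict(
                CohortRecord(
                    subject_id=f"P{i+1:03d}",
                    sex=sexes[i],
                    age_years=round(float(ages[order[i]]), 2),
                    diagnosis=row["diagnosis"],
                    rvot_type=row["rvot_type"],
                    dysfunction=row["dysfunction"],
                )
            )
        )
    return pd.DataFrame(records)


def build_screening_log() -> pd.DataFrame:
    """Deterministic 100-patient screening log: the 81 included subjects
    followed by the 19 exclusions with their recorded reasons."""
    included = build_cohort_table()
    rows = list(included.to_dict("records"))
    i = len(rows)
    for flag, count in _EXCLUSION_COUNTS.items():
        for _ in range(count):
            i += 1
            rows.append(
                asdict(
                    CohortRecord(
                        subject_id=f"P{i:03d}",
                        sex="M" if i % 2 == 1 else "F",
                        age_years=14.5,
                        diagnosis="ToF",
                        rvot_type="TAP",
                        dysfunction="Regurgitant",
                        exclusion_flag=flag,
                    )
                )
            )
    df = pd.DataFrame(rows)
    assert len(df) == 100
    return df
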