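"""Geometric measurements: landmarks, centreline length, diameter profile.

The variables mirror those used clinically for device sizing in the
right ventricular outflow tract: total surface area (SA), trunk
centreline length from the proximal opening to the bifurcation
(L_RVOT), and perimeter-derived diameters (cross-section perimeter / pi)
sampled at 1 mm increments along the straight line from the inlet
centroid to the bifurcation saddle, averaged into D_AVE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh
from .centerline import Centreline, cross_section, _point_in_loop


@dataclass
class LandmarkSet:
    """Anatomical landmarks: centreline ends + bifurcation point."""

    proximal: np.ndarray
    lpa_end: np.ndarray
    rpa_end: np.ndarray
    bifurcation: np.ndarray

    def __post_init__(self):
        for name in ("proximal", "lpa_end", "rpa_end", "bifurcation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())

    def as_array(self) -> np.ndarray:
        """Fixed correspondence order (proximal, lpa, rpa, bifurcation)."""
        return np.vstack([self.proximal, self.lpa_end, self.rpa_end, self.bifurcation])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LandmarkSet":
        arr = self.as_array() @ R.T + t
        return LandmarkSet(*arr)


@dataclass
class GeometricSummary:
    """Per-subject geometric variables (mm / mm²)."""

    sa: float
    l_rvot: float
    profile: np.ndarray  # (k, 2): arc position (mm, 1 mm steps), diameter (mm)
    d_ave: float

    def validate(self) -> None:
        pos = self.profile[:, 0]
        dia = self.profile[:, 1]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("profile positions must be strictly increasing")
        if np.any(dia <= 0):
            raise ValueError("profile diameters must be positive")
        if not np.isclose(self.d_ave, dia.mean()):
            raise ValueError("d_ave must equal the mean profile diameter")

    def as_row(self, subject_id: str | None = None) -> dict:
        row = dict(sa=self.sa, l_rvot=self.l_rvot, d_ave=self.d_ave)
        if subject_id is not None:
            row = {"subject_id": subject_id, **row}
        return row


def extract_landmarks(centreline: Centreline) -> LandmarkSet:
    """Landmarks = first trunk point, branch ends, bifurcation point."""
    for name, br in centreline.branches().items():
        if len(br.points) < 2:
            raise ValueError(f"missing branch {name}")
    return LandmarkSet(
        proximal=centreline.trunk.points[0],
        lpa_end=centreline.branch_lpa.points[-1],
        rpa_end=centreline.branch_rpa.points[-1],
        bifurcation=centreline.bifurcation_point,
    )


def rvot_length(centreline: Centreline) -> float:
    """Trunk centreline arc length from proximal landmark to bifurcation (mm)."""
    return centreline.trunk.length


def bifurcation_saddle(mesh: SurfaceMesh, centreline: Centreline) -> np.ndarray:
    """Locate the saddle ridge point between the two branch openings.

    Operationally: at the plane where the swept cross-section first splits
    into two closed curves, the saddle is the midpoint of the closest pair
    of points between the two curves, projected onto the surface.
    """
    from .geometry import nearest_on_surface

    bif = centreline.bifurcation_point
    tangent = centreline.trunk.tangent_at(centreline.trunk.length)
    # step slightly past the bifurcation to find a split section
    r_here = float(centreline.trunk.radius[-1])
    for frac in (0.15, 0.3, 0.5, 0.8):
        origin = bif + frac * r_here * tangent
        comps = [c for c in cross_section(mesh, origin, tangent) if c["closed"]]
        comps = [c for c in comps if np.linalg.norm(c["centroid"] - origin) < 4 * r_here]
        if len(comps) >= 2:
            comps = sorted(comps, key=lambda c: -c["perimeter"])[:2]
            a, b = comps[0]["points"], comps[1]["points"]
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            mid = 0.5 * (a[i] + b[j])
            return nearest_on_surface(mesh, mid)[0][0]
    # no split found (degenerate tube): fall back to the bifurcation point
    return np.asarray(bif, float)


def diameter_profile(
    mesh: SurfaceMesh,
    inlet_centroid: np.ndarray,
    bifurcation_saddle: np.ndarray,
    step: float = 1.0,
) -> np.ndarray:
    """Perimeter-derived diameters at fixed increments along the axis line.

    Planes are orthogonal to the straight line from the inlet centroid to
    the bifurcation saddle; at each plane the closed cross-section curve
    enclosing the line contributes diameter = perimeter / pi.  Sections
    whose intersection touches an opening (open curves) are discarded.

    Returns (k, 2) array of (position mm, diameter mm).
    """
    p0 = np.asarray(inlet_centroid, float)
    p1 = np.asarray(bifurcation_saddle, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < step:
        raise ValueError("axis line shorter than one step")
    axis = axis / length
    tm = mesh.to_trimesh()
    rows = []
    positions = np.arange(step, length, step)
    for s in positions:
        q = p0 + s * axis
        comps = cross_section(mesh, q, axis, tm=tm)
        closed = [c for c in comps if c["closed"]]
        if len(closed) < len(comps):
            # an open curve at this station means the plane crossed an
            # opening; discard the station entirely (opening-exclusion rule)
            near_open = [
                c
                for c in comps
                if not c["closed"]
                and np.linalg.norm(c["centroid"] - q) < 0.75 * length
            ]
            if near_open:
                continue
        enc = None
        for c in closed:
            if _point_in_loop(c["points"], q, axis):
                enc = c
                break
        if enc is None:
            continue
        rows.append((float(s), enc["perimeter"] / np.pi))
    if not rows:
        raise ValueError("no valid cross-section along the axis line")
    return np.asarray(rows)


def geometric_summary(
    mesh: SurfaceMesh,
    centreline: Centreline,
    step: float = 1.0,
    saddle: np.ndarray | None = None,
) -> GeometricSummary:
    """Bundle SA, L_RVOT, the diameter profile and D_AVE for one subject."""
    from .meshops import surface_area

    sa = surface_area(mesh)
    l_rvot = rvot_length(centreline)
    if saddle is None:
        saddle = bifurcation_saddle(mesh, centreline)
    inlet = centreline.trunk.points[0]
    prof = diameter_profile(mesh, inlet, saddle, step=step)
    summary = GeometricSummary(
        sa=sa, l_rvot=l_rvot, profile=prof, d_ave=float(prof[:, 1].mean())
    )
    summary.validate()
    return summary


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    """One CSV-ready row per subject keyed by subject_id."""
    return pd.DataFrame(
        [s.as_row(sid) for sid, s in summaries.items()]
    )


def profile_to_frame(summary: GeometricSummary) -> pd.DataFrame:
    return pd.DataFrame(summary.profile, columns=["position_mm", "diameter_mm"])
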