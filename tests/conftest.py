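import numpy as np
import pytest

from rvotshape import synthetic as syn
from rvotshape.centerline import compute_centreline
from rvotshape.geometry import SurfaceMesh


@pytest.fixture(scope="session")
def default_shape():
    """One default synthetic Y-vessel with ground truth."""
    return syn.generate_shape(syn.ShapeParams(), seed=0)


@pytest.fixture(scope="session")
def cylinder():
    """Open straight cylinder r=10 mm, L=50 mm (degenerate test mode)."""
    params = syn.ShapeParams(
        taper=0.0,
        bulge_amp=0.0,
        curv_frontal=0.0,
        curv_sagittal=0.0,
        inlet_ellipticity=1.0,
        r_inlet=10.0,
        trunk_length=50.0,
    )
    return syn.generate_shape(params, suppress_branches=True)


@pytest.fixture(scope="session")
def default_centreline(default_shape):
    mesh, _, _ = default_shape
    return compute_centreline(mesh, step=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six generated subjects with ground truth (kept small for speed)."""
    pop = syn.sample_population(6, seed=5)
    out = []
    for i, (params, rec) in enumerate(pop):
        mesh, cl, lm = syn.generate_shape(
            params, axial_samples=32, circumferential_samples=24, seed=5 + i
        )
        out.append(dict(params=params, record=rec, mesh=mesh, centreline=cl, landmarks=lm))
    return out


@pytest.fixture(scope="session")
def sphere_mesh():
    import trimesh

    m = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(2))
    m.vertices = m.vertices * 10.0
    return m


def brute_force_area(mesh: SurfaceMesh) -> float:
    """Independent per-triangle cross-product loop (test oracle)."""
    total = 0.0
    for f in mesh.faces:
        a, b, c = mesh.vertices[f]
        total += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
    return total
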