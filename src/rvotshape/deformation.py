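"""Control-point/momenta diffeomorphic flows and the varifold metric.

Deformations are parameterised by a sparse set of control points carrying
momentum vectors.  A Gaussian kernel ``K(x, y) = exp(-|x - y|^2 / sigma^2)``
turns the momenta into a smooth velocity field; control points and momenta
evolve by the Hamiltonian system

    dc_i/dt =  dH/da_i = sum_j K(c_i, c_j) a_j
    da_i/dt = -dH/dc_i

with ``H = 1/2 sum_ij a_i . a_j K(c_i, c_j)``, integrated with explicit
Euler steps; arbitrary points are transported through the resulting
velocity field.  Gradients of a loss on the transported points with
respect to the initial momenta (and the points themselves) are computed
with a hand-written discrete adjoint of the Euler scheme.

Surfaces are compared with a varifold distance: each triangle contributes
its centre and area-weighted normal, and

    <A, B> = sum_{f in A, g in B} k(x_f, x_g) (N_f . N_g)^2 / (|N_f| |N_g|)

with a Gaussian spatial kernel ``k`` of width ``sigma_var``.  The squared
normal alignment makes the distance orientation-insensitive and
correspondence-free.
"""

from __future__ import annotations

import numpy as np


# ----------------------------------------------------------------------
# Gaussian kernel helpers


def _gauss(sq_dist, sigma):
    return np.exp(-sq_dist / (sigma * sigma))


def _pairwise_sq(x, y):
    d = x[:, None, :] - y[None, :, :]
    return d, (d * d).sum(-1)


def kernel_matrix(x, y, sigma):
    _, sq = _pairwise_sq(np.asarray(x, float), np.asarray(y, float))
    return _gauss(sq, sigma)


def hamiltonian(c, a, sigma) -> float:
    """Deformation energy 1/2 a^T K(c, c) a."""
    K = kernel_matrix(c, c, sigma)
    return 0.5 * float(np.einsum("ij,id,jd->", K, a, a))


def hamiltonian_grad_momenta(c, a, sigma) -> np.ndarray:
    return kernel_matrix(c, c, sigma) @ a


# ----------------------------------------------------------------------
# forward flow


def _rhs(c, a, y, sigma):
    """Time derivatives (dc, da, dy) of the Hamiltonian system."""
    s2 = sigma * sigma
    D, sq = _pairwise_sq(c, c)
    K = _gauss(sq, sigma)
    dc = K @ a
    P = a @ a.T  # (n, n) momentum inner products
    da = (2.0 / s2) * np.einsum("ij,ij,ijd->id", P, K, D)
    Dy, sqy = _pairwise_sq(y, c)
    Ky = _gauss(sqy, sigma)
    dy = Ky @ a
    return dc, da, dy


def flow(points, control_points, momenta, sigma_def, n_time_steps=10):
    """Transport ``points`` through the momenta-parameterised flow.

    Zero momenta return the input exactly.  Raises on non-finite values
    during integration, naming the offending step.
    """
    y = np.asarray(points, float).copy()
    c = np.asarray(control_points, float).copy()
    a = np.asarray(momenta, float).copy()
    if c.shape != a.shape:
        raise ValueError("momenta count must match control-point count")
    if n_time_steps < 1:
        raise ValueError("n_time_steps must be >= 1")
    if not np.any(a):
        return y
    h = 1.0 / n_time_steps
    for k in range(n_time_steps):
        dc, da, dy = _rhs(c, a, y, sigma_def)
        c = c + h * dc
        a = a + h * da
        y = y + h * dy
        if not (np.isfinite(c).all() and np.isfinite(a).all() and np.isfinite(y).all()):
            raise FloatingPointError(f"non-finite values at integration step {k}")
    return y


class FlowTape:
    """Forward flow with stored trajectory and a reverse-mode backward pass."""

    def __init__(self, points, control_points, momenta, sigma, n_time_steps=10):
        self.sigma = float(sigma)
        self.h = 1.0 / n_time_steps
        self.n_steps = int(n_time_steps)
        self.traj = [(
            np.asarray(control_points, float).copy(),
            np.asarray(momenta, float).copy(),
            np.asarray(points, float).copy(),
        )]
        for k in range(self.n_steps):
            c, a, y = self.traj[-1]
            dc, da, dy = _rhs(c, a, y, self.sigma)
            self.traj.append((c + self.h * dc, a + self.h * da, y + self.h * dy))

    @property
    def points(self):
        return self.traj[-1][2]

    def backward(self, gy_final):
        """Pull a cotangent on the final points back to t=0.

        Returns (grad_momenta, grad_points, grad_controls) at t=0.
        """
        s2 = self.sigma * self.sigma
        gc = np.zeros_like(self.traj[0][0])
        ga = np.zeros_like(self.traj[0][1])
        gy = np.asarray(gy_final, float).copy()
        h = self.h
        for k in range(self.n_steps - 1, -1, -1):
            c, a, y = self.traj[k]
            D, sq = _pairwise_sq(c, c)
            K = _gauss(sq, self.sigma)
            P = a @ a.T
            Dy, sqy = _pairwise_sq(y, c)
            Ky = _gauss(sqy, self.sigma)

            gc_new = gc.copy()
            ga_new = ga.copy()
            gy_new = gy.copy()

            # --- dc = K @ a ------------------------------------------------
            # wrt a
            ga_new += h * (K.T @ gc)
            # wrt c: S_ij = gc_i . a_j
            S = gc @ a.T
            gc_new += h * (-2.0 / s2) * np.einsum("ij,ij,ijd->id", S + S.T, K, D)

            # --- da = (2/s2) sum_j P_ij K_ij D_ij --------------------------
            T = np.einsum("id,ijd->ij", ga, D)  # ga_i . D_ij
            # wrt a
            ga_new += h * (2.0 / s2) * np.einsum("ij,ij,jd->id", T + T.T, K, a)
            # wrt c (through D and K)
            gc_new += h * (2.0 / s2) * (
                np.einsum("ij,ij,id->id", P, K, ga)
                - np.einsum("ij,ij,jd->id", P, K, ga)
            )
            gc_new += h * (-4.0 / (s2 * s2)) * np.einsum(
                "ij,ij,ij,ijd->id", P, T + T.T, K, D
            )

            # --- dy = Ky @ a ----------------------------------------------
            ga_new += h * (Ky.T @ gy)
            Sy = gy @ a.T  # (m, n): gy_p . a_j
            gy_new += h * (-2.0 / s2) * np.einsum("pj,pj,pjd->pd", Sy, Ky, Dy)
            gc_new += h * (2.0 / s2) * np.einsum("pj,pj,pjd->jd", Sy, Ky, Dy)

            gc, ga, gy = gc_new, ga_new, gy_new
        return ga, gy, gc


# ----------------------------------------------------------------------
# varifold metric


def varifold_repr(vertices, faces):
    """Triangle centres and area-weighted normals of a surface."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    x = v[f].mean(axis=1)
    N = 0.5 * np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return x, N


def _inner(xa, Na, xb, Nb, sigma):
    _, sq = _pairwise_sq(xa, xb)
    k = _gauss(sq, sigma)
    dot = Na @ Nb.T
    na = np.linalg.norm(Na, axis=1)
    nb = np.linalg.norm(Nb, axis=1)
    denom = np.outer(na, nb)
    denom = np.where(denom > 0, denom, 1.0)
    return float((k * dot * dot / denom).sum())


def varifold_distance(mesh_a, mesh_b, sigma_var) -> float:
    """Squared varifold distance |A - B|^2 >= 0, symmetric, zero iff equal."""
    xa, Na = varifold_repr(mesh_a.vertices, mesh_a.faces)
    xb, Nb = varifold_repr(mesh_b.vertices, mesh_b.faces)
    d = (
        _inner(xa, Na, xa, Na, sigma_var)
        + _inner(xb, Nb, xb, Nb, sigma_var)
        - 2.0 * _inner(xa, Na, xb, Nb, sigma_var)
    )
    return max(d, 0.0)


def _inner_grad_first(xa, Na, xb, Nb, sigma):
    """<A, B> and its partials wrt the first argument's centres/normals."""
    s2 = sigma * sigma
    D, sq = _pairwise_sq(xa, xb)
    k = _gauss(sq, sigma)
    dot = Na @ Nb.T
    na = np.linalg.norm(Na, axis=1)
    nb = np.linalg.norm(Nb, axis=1)
    na_s = np.where(na > 0, na, 1.0)
    denom = np.outer(na_s, nb)
    denom = np.where(denom > 0, denom, 1.0)
    P = dot * dot / denom
    val = float((k * P).sum())
    gx = (-2.0 / s2) * np.einsum("fg,fg,fgd->fd", k, P, D)
    # dP/dNa_f = 2 dot_fg Nb_g / denom - dot^2 Na_f / (na^2 denom)
    gN = 2.0 * np.einsum("fg,fg,gd->fd", k, dot / denom, Nb)
    gN -= np.einsum("fg,f,fd->fd", k * dot * dot / denom, 1.0 / (na_s * na_s), Na)
    return val, gx, gN


def _chain_to_vertices(vertices, faces, gx, gN):
    """Chain centre/normal cotangents back to vertex positions."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    grad = np.zeros_like(v)
    # centres: each vertex gets a third
    for i in range(3):
        np.add.at(grad, f[:, i], gx / 3.0)
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    g1 = 0.5 * np.cross(e2, gN)
    g2 = 0.5 * np.cross(gN, e1)
    np.add.at(grad, f[:, 0], -(g1 + g2))
    np.add.at(grad, f[:, 1], g1)
    np.add.at(grad, f[:, 2], g2)
    return grad


def varifold_loss_grad(vertices_a, faces_a, target_repr, sigma_var):
    """Data term |A - B|^2 (up to the constant <B,B>) and grad wrt A's vertices.

    ``target_repr`` is the (centres, normals) pair of the fixed target.
    """
    xb, Nb = target_repr
    xa, Na = varifold_repr(vertices_a, faces_a)
    vaa, gx_aa, gN_aa = _inner_grad_first(xa, Na, xa, Na, sigma_var)
    vab, gx_ab, gN_ab = _inner_grad_first(xa, Na, xb, Nb, sigma_var)
    loss = vaa - 2.0 * vab
    gx = 2.0 * gx_aa - 2.0 * gx_ab
    gN = 2.0 * gN_aa - 2.0 * gN_ab
    grad = _chain_to_vertices(vertices_a, faces_a, gx, gN)
    return loss, grad
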