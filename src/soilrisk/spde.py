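"""Finite-element SPDE representation of a Matérn (nu = 1) Gaussian field.

A Matérn field with smoothness nu = 1 in two dimensions solves the SPDE
(kappa^2 - Laplacian) x(s) = W(s) / tau up to scaling; discretising with
piecewise-linear finite elements on a triangulation yields a Gaussian
Markov random field on the mesh vertices with sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

where C is the (lumped, diagonal) mass matrix and G the stiffness matrix.
The stationary marginal variance is sigma^2 = 1 / (4 pi kappa^2 tau^2) and
the practical range is rho = sqrt(8) / kappa.  A sparse barycentric
projector A maps vertex weights to field values at arbitrary locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .mesh import Mesh


def fem_matrices(mesh: Mesh) -> tuple:
    """Lumped mass matrix C (diagonal) and stiffness matrix G (sparse CSC)."""
    verts, tris = mesh.vertices, mesh.triangles
    n = len(verts)
    areas = mesh.triangle_areas()
    c_diag = np.zeros(n)
    rows, cols, vals = [], [], []
    p = verts[tris]  # (m, 3, 2)
    # edge vectors opposite each vertex
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    for t in range(3):
        np.add.at(c_diag, tris[:, t], areas / 3.0)
    for a in range(3):
        for b in range(3):
            val = (e[:, a, :] * e[:, b, :]).sum(axis=1) / (4.0 * areas)
            rows.append(tris[:, a])
            cols.append(tris[:, b])
            vals.append(val)
    G = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    C = sp.diags(c_diag, format="csc")
    return C, G


@dataclass
class SpdeOperator:
    """Assembled SPDE precision with its factorisation helpers."""

    mesh: Mesh
    C: sp.csc_matrix
    G: sp.csc_matrix
    kappa: float
    tau: float
    Q: sp.csc_matrix

    @property
    def marginal_sd(self) -> float:
        """Analytic stationary marginal SD, 1 / sqrt(4 pi kappa^2 tau^2)."""
        return 1.0 / np.sqrt(4.0 * np.pi * self.kappa**2 * self.tau**2)

    def factor(self, jitter: float = 1e-8):
        Qj = (self.Q + jitter * sp.eye(self.Q.shape[0], format="csc")).tocsc()
        try:
            return splu(Qj)
        except RuntimeError as exc:
            raise ValueError(f"precision factorisation failed: {exc}") from exc

    def marginal_variance(self, indices) -> np.ndarray:
        """Exact diag(Q^-1) entries at selected vertices via sparse solves."""
        lu = self.factor()
        n = self.Q.shape[0]
        out = np.empty(len(indices))
        for k, i in enumerate(indices):
            e = np.zeros(n)
            e[i] = 1.0
            out[k] = lu.solve(e)[i]
        return out

    def correlation(self, i: int, j: int) -> float:
        """Correlation between vertices i and j implied by Q^-1."""
        lu = self.factor()
        n = self.Q.shape[0]
        ei = np.zeros(n)
        ei[i] = 1.0
        col = lu.solve(ei)
        ej = np.zeros(n)
        ej[j] = 1.0
        vj = lu.solve(ej)[j]
        return float(col[j] / np.sqrt(col[i] * vj))

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Exact draws x ~ N(0, Q^-1) via dense Cholesky (small meshes)."""
        Qd = self.Q.toarray()
        Qd[np.diag_indices_from(Qd)] += 1e-8
        L = np.linalg.cholesky(Qd)
        z = rng.standard_normal((n_draws, Qd.shape[0]))
        from scipy.linalg import solve_triangular

        return solve_triangular(L.T, z.T, lower=False).T


def assemble_spde(mesh: Mesh, kappa: float, tau: float) -> SpdeOperator:
    """Assemble the alpha = 2 precision Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)."""
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be > 0")
    C, G = fem_matrices(mesh)
    cinv = sp.diags(1.0 / C.diagonal(), format="csc")
    Q = (tau**2) * (kappa**4 * C + 2.0 * kappa**2 * G + G @ cinv @ G)
    Q = ((Q + Q.T) * 0.5).tocsc()
    return SpdeOperator(mesh, C, G, kappa, tau, Q)


def kappa_tau_from(range_km: float, marginal_sd: float) -> tuple:
    """Map (practical range, marginal SD) to SPDE (kappa, tau)."""
    kappa = np.sqrt(8.0) / range_km
    tau = 1.0 / (np.sqrt(4.0 * np.pi) * kappa * marginal_sd)
    return kappa, tau


@dataclass
class Projector:
    """Sparse barycentric projector from mesh vertices to point locations.

    ``A`` has one row per point with at most three nonzero weights summing
    to one; rows for points outside the mesh are empty and flagged in
    ``outside``.
    """

    A: sp.csr_matrix
    outside: np.ndarray

    def project(self, vertex_values: np.ndarray) -> np.ndarray:
        return self.A @ vertex_values


def make_projector(mesh: Mesh, points, strict: bool = False) -> Projector:
    """Barycentric interpolation weights for each point's containing triangle.

    Point location uses a Delaunay walk over the mesh vertex set; triangles
    that were dropped from the mesh (outside the extension) mark their
    points as outside.  In ``strict`` mode an outside point raises.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    dela = Delaunay(mesh.vertices)
    simplex = dela.find_simplex(points)
    n_pts, n_vert = len(points), mesh.n_vertices
    rows, cols, vals = [], [], []
    outside = np.zeros(n_pts, dtype=bool)
    for k in range(n_pts):
        s = simplex[k]
        if s < 0:
            outside[k] = True
            continue
        tri_verts = dela.simplices[s]
        if tuple(sorted(tri_verts)) not in mesh._tri_keys:
            outside[k] = True
            continue
        T = dela.transform[s]
        bary2 = T[:2] @ (points[k] - T[2])
        bary = np.append(bary2, 1.0 - bary2.sum())
        bary = np.clip(bary, 0.0, 1.0)
        bary = bary / bary.sum()
        rows.extend([k] * 3)
        cols.extend(tri_verts)
        vals.extend(bary)
    if strict and outside.any():
        raise ValueError(f"{int(outside.sum())} points fall outside the mesh")
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_pts, n_vert))
    return Projector(A=A, outside=outside)


def field_proxy_score(
    mesh: Mesh,
    sample_xy: np.ndarray,
    log_conc: np.ndarray,
    range_km: float,
    marginal_sd: float,
    sigma_x: float,
    criterion: str = "dic",
) -> float:
    """Information criterion of the Gaussian field-only model on a mesh.

    Observation model: y = mu + A w + e, w ~ N(0, Q^-1), e ~ N(0, sigma_x^2 I),
    with fixed hyperparameters.  The posterior of w is Gaussian in closed
    form, so DIC (default) and WAIC have closed expressions; used as the
    cheap proxy when choosing the mesh resolution.
    """
    y = np.asarray(log_conc, dtype=float)
    mu = y.mean()
    r = y - mu
    kappa, tau = kappa_tau_from(range_km, marginal_sd)
    op = assemble_spde(mesh, kappa, tau)
    proj = make_projector(mesh, sample_xy)
    if proj.outside.any():
        raise ValueError("mesh does not cover all sampling locations")
    A = proj.A
    prec = (op.Q + (A.T @ A) / sigma_x**2).tocsc()
    lu = splu(prec + 1e-10 * sp.eye(prec.shape[0], format="csc"))
    w_hat = lu.solve(np.asarray(A.T @ r / sigma_x**2).ravel())
    fitted = A @ w_hat
    n = len(y)
    # pointwise posterior predictive variance: sigma_x^2 + a_i' Sigma a_i
    At = A.T.toarray() if A.shape[0] <= 4000 else None
    if At is not None:
        sol = np.column_stack([lu.solve(At[:, i]) for i in range(A.shape[0])])
        pred_var = sigma_x**2 + np.einsum("ij,ij->j", At, sol)
    else:  # pragma: no cover - large-problem fallback
        pred_var = np.full(n, sigma_x**2)
    resid = r - fitted
    if criterion == "dic":
        dev_hat = np.sum(resid**2 / sigma_x**2 + np.log(2 * np.pi * sigma_x**2))
        p_d = np.sum((pred_var - sigma_x**2) / sigma_x**2)  # tr(A Sigma A') / sigma^2
        return float(dev_hat + 2.0 * p_d)
    if criterion == "waic":
        lppd = -0.5 * np.sum(
            np.log(2 * np.pi * pred_var) + resid**2 / pred_var
        )
        p_waic = np.sum((pred_var - sigma_x**2) / pred_var)
        return float(-2.0 * (lppd - p_waic))
    raise ValueError(f"unknown criterion {criterion!r}")
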