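"""Linear (P1) triangular finite-element assembly on numpy/scipy.sparse.

Provides the small set of operators the flow and transport solvers need:
mass (consistent and lumped), stiffness with per-element coefficients,
convection for a nodal velocity field, streamline-upwind (SUPG) stabilization
for advection-dominated species, boundary integrals along tagged exterior
edges, and Dirichlet row elimination.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tri_geometry(points: np.ndarray, triangles: np.ndarray):
    """Element areas and constant P1 basis gradients.

    Returns (areas (M,), grads (M, 3, 2)) with grads[e, i] = grad of the
    basis function of local node i on element e.
    """
    p = points[triangles]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    det = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    areas = 0.5 * np.abs(det)
    grads = np.stack([b, c], axis=2) / det[:, None, None]
    return areas, grads


def _assemble(triangles, local, n):
    """Scatter (M, 3, 3) local matrices into a CSR matrix."""
    rows = np.repeat(triangles, 3, axis=1).ravel()
    cols = np.tile(triangles, (1, 3)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def stiffness(points, triangles, coeff=1.0):
    """Assemble ∫ k ∇u·∇v with per-element (or scalar) coefficient k."""
    areas, grads = tri_geometry(points, triangles)
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), areas.shape)
    local = np.einsum("e,eid,ejd->eij", coeff * areas, grads, grads)
    return _assemble(triangles, local, len(points))


_MLOC = (np.ones((3, 3)) + np.eye(3)) / 12.0


def mass(points, triangles, lumped=False, element_mask=None):
    """Consistent (or lumped) mass matrix; optionally restricted to a subset of elements."""
    areas, _ = tri_geometry(points, triangles)
    if element_mask is not None:
        areas = np.where(element_mask, areas, 0.0)
    local = areas[:, None, None] * _MLOC
    M = _assemble(triangles, local, len(points))
    if lumped:
        return np.asarray(M.sum(axis=1)).ravel()
    return M


def convection(points, triangles, u_nodes):
    """Assemble C[i,j] = ∫ (u·∇φ_j) φ_i for a P1 nodal velocity field."""
    areas, grads = tri_geometry(points, triangles)
    ue = u_nodes[triangles]                       # (M, 3, 2)
    # ∫ φ_i (u·∇φ_j) = ∇φ_j · Σ_k u_k ∫ φ_i φ_k  (exact for P1 u)
    w = np.einsum("ik,ekd->eid", _MLOC, ue)       # (M, 3, 2): Σ_k Mloc[i,k] u_k
    local = areas[:, None, None] * np.einsum("eid,ejd->eij", w, grads)
    return _assemble(triangles, local, len(points))


def gradient_ops(points, triangles, element_mask=None):
    """C_x[i,j] = ∫ φ_i ∂φ_j/∂x and the y analogue (for Stokes div/grad blocks)."""
    areas, grads = tri_geometry(points, triangles)
    if element_mask is not None:
        areas = np.where(element_mask, areas, 0.0)
    out = []
    for d in (0, 1):
        local = (areas / 3.0)[:, None, None] * np.broadcast_to(
            grads[:, None, :, d], (len(areas), 3, 3))
        out.append(_assemble(triangles, local, len(points)))
    return out


def supg(points, triangles, u_nodes, diffusivity):
    """Streamline-diffusion stabilization Σ_e τ_e ∫ (u·∇φ_i)(u·∇φ_j).

    τ_e = (h_e / 2|u|) (coth Pe − 1/Pe) with element Péclet Pe = |u| h_e / 2D.
    Zero where the element velocity vanishes (solid subdomains).
    """
    areas, grads = tri_geometry(points, triangles)
    ue = u_nodes[triangles].mean(axis=1)          # element mean velocity
    speed = np.hypot(ue[:, 0], ue[:, 1])
    h = np.sqrt(4.0 * areas / np.sqrt(3.0))
    D = np.broadcast_to(np.asarray(diffusivity, dtype=float), areas.shape)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        pe = speed * h / (2.0 * D)
        alpha = np.where(pe > 1e-8, 1.0 / np.tanh(np.minimum(pe, 50.0)) - 1.0 / pe, 0.0)
        tau = np.where(speed > 0, h / (2.0 * np.maximum(speed, 1e-300)) * alpha, 0.0)
    udg = np.einsum("ed,eid->ei", ue, grads)      # u·∇φ_i per element
    local = (tau * areas)[:, None, None] * np.einsum("ei,ej->eij", udg, udg)
    return _assemble(triangles, local, len(points))


def boundary_convection(points, edges, u_n, n_nodes):
    """Boundary matrix B[i,j] = ∮ φ_i φ_j (u·n) dΓ for the conservative
    convection form, exact for P1 traces (triple product of P1 functions)."""
    le = edge_lengths(points, edges)
    a, b = edges[:, 0], edges[:, 1]
    ua, ub = u_n[a], u_n[b]
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([a, b, b, a])
    off = le * (ua + ub) / 12.0
    vals = np.concatenate([le * (3 * ua + ub) / 12.0,
                           le * (ua + 3 * ub) / 12.0, off, off])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()


def edge_lengths(points, edges):
    d = points[edges[:, 1]] - points[edges[:, 0]]
    return np.hypot(d[:, 0], d[:, 1])


def boundary_product_integral(points, edges, f, g):
    """∮ f g dΓ over the given edges, exact for P1 traces of f and g."""
    le = edge_lengths(points, edges)
    fi, fj = f[edges[:, 0]], f[edges[:, 1]]
    gi, gj = g[edges[:, 0]], g[edges[:, 1]]
    return float(np.sum(le / 6.0 * (2 * fi * gi + fi * gj + fj * gi + 2 * fj * gj)))


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray, values):
    """Replace rows `nodes` of A x = b with identity rows x = value."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[nodes] = 0.0
    ind = np.zeros(n)
    ind[nodes] = 1.0
    A2 = sp.diags(keep) @ A + sp.diags(ind)
    b2 = keep * b
    b2[nodes] = values
    return A2.tocsr(), b2
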