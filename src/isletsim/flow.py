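"""Steady incompressible flow in the perifusion chamber lumen.

At the perifusion operating point (v_in = 1e-4 m/s in a 4 mm channel,
Re ≈ 0.6) the flow is creeping, so the default solver is steady Stokes;
the full Navier-Stokes convective term can be enabled and is resolved by
Picard iteration.  Discretization is equal-order P1-P1 with
Brezzi-Pitkäranta pressure stabilization.  Boundary conditions: parabolic
inflow at the inlet, no slip on walls and on all liquid-solid interfaces
(islet and capsule surfaces), pressure/no-viscous-stress (p0 = 0) at the
outlet.  The velocity is identically zero in solid subdomains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import INLET, LUMEN, OUTLET, WALL, Mesh

__all__ = ["FlowParams", "VelocityField", "inlet_profile", "solve_steady_flow"]


class FlowSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FlowParams:
    """Perifusion medium at body temperature and the inflow speed."""

    density: float = 993.0          # kg m^-3
    viscosity: float = 0.7e-3       # Pa s
    v_in: float = 1.0e-4            # m s^-1, peak of the parabolic inlet profile
    body_force: tuple[float, float] = (0.0, 0.0)   # N m^-3

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0 or self.v_in <= 0:
            raise ValueError("density, viscosity and v_in must all be > 0")


@dataclass
class VelocityField:
    """Nodal velocity/pressure of the steady lumen flow."""

    u: np.ndarray               # (N, 2) m/s; exactly zero in solid subdomains
    p: np.ndarray               # (N,) Pa
    reynolds: float
    diagnostics: dict = field(default_factory=dict)


def inlet_profile(s, v_in: float = 1.0e-4):
    """Parabolic inflow speed 4 v_in s (1 - s) for normalized coordinate s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("inlet coordinate s must lie in [0, 1]")
    return 4.0 * v_in * s * (1.0 - s)


def solve_steady_flow(mesh: Mesh, params: FlowParams | None = None,
                      navier_stokes: bool = False, picard_tol: float = 1e-8,
                      max_picard: int = 30) -> VelocityField:
    """Solve the steady flow once per geometry; species transport reuses it."""
    params = params or FlowParams()
    pts, tris = mesh.points, mesh.triangles
    n = mesh.n_nodes
    lumen = mesh.subdomain == LUMEN
    solid = ~lumen

    K = fem.stiffness(pts, tris, np.where(lumen, 1.0, 0.0))
    Cx, Cy = fem.gradient_ops(pts, tris, element_mask=lumen)
    areas, _ = fem.tri_geometry(pts, tris)
    h2 = 4.0 * areas / np.sqrt(3.0)
    beta = 0.01
    Sp = fem.stiffness(pts, tris, np.where(lumen, beta * h2 / params.viscosity, 0.0))

    # Dirichlet velocity nodes: inlet (parabolic), walls, solid interfaces & interiors
    inlet_nodes = mesh.boundary_nodes(INLET)
    wall_nodes = mesh.boundary_nodes(WALL)
    solid_nodes = np.unique(tris[solid]) if solid.any() else np.array([], dtype=int)
    lumen_nodes = np.unique(tris[lumen])
    unused = np.setdiff1d(np.arange(n), lumen_nodes)

    s = pts[inlet_nodes, 1] / mesh.chamber.height
    ux_in = inlet_profile(s, params.v_in)

    dir_nodes = np.concatenate([inlet_nodes, wall_nodes, solid_nodes, unused])
    dir_ux = np.concatenate([ux_in, np.zeros(len(wall_nodes) + len(solid_nodes) + len(unused))])
    dir_nodes, first = np.unique(dir_nodes, return_index=True)
    dir_ux = dir_ux[first]     # inlet values win at inlet corners (s=0 there anyway)

    eta = params.viscosity
    fx = np.zeros(n)
    fy = np.zeros(n)
    if any(params.body_force):
        Ml = fem.mass(pts, tris, lumped=True, element_mask=lumen)
        fx = Ml * params.body_force[0]
        fy = Ml * params.body_force[1]

    # pressure DOFs at nodes untouched by lumen elements are pinned to zero
    p_pin = unused

    u = np.zeros((n, 2))
    n_iter = 1 if not navier_stokes else max_picard
    for it in range(n_iter):
        if navier_stokes:
            # convection assembled on the full mesh; u is zero in solids so
            # no spurious terms arise there
            Auu = eta * K + params.density * fem.convection(pts, tris, u)
        else:
            Auu = eta * K
        A = sp.bmat([[Auu, None, -Cx.T],
                     [None, Auu, -Cy.T],
                     [Cx, Cy, Sp]], format="csr")
        b = np.concatenate([fx, fy, np.zeros(n)])
        A, b = fem.apply_dirichlet(A, b, dir_nodes, dir_ux)                  # u_x rows
        A, b = fem.apply_dirichlet(A, b, n + dir_nodes, np.zeros(len(dir_nodes)))  # u_y rows
        A, b = fem.apply_dirichlet(A, b, 2 * n + p_pin, np.zeros(len(p_pin)))
        try:
            sol = spla.spsolve(A.tocsc(), b)
        except Exception as exc:  # pragma: no cover
            raise FlowSolverError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise FlowSolverError("flow solve produced non-finite values")
        u_new = np.column_stack([sol[:n], sol[n:2 * n]])
        du = np.linalg.norm(u_new - u) / max(np.linalg.norm(u_new), 1e-300)
        u = u_new
        p = sol[2 * n:]
        if not navier_stokes or du < picard_tol:
            break
    else:  # pragma: no cover
        raise FlowSolverError(f"Picard iteration did not converge (last update {du:.2e})")

    u[solid_nodes] = 0.0
    div_res = np.linalg.norm(Cx @ u[:, 0] + Cy @ u[:, 1] + Sp @ p)
    inflow = flux_through(mesh, u, INLET)
    outflow = flux_through(mesh, u, OUTLET)
    re = params.density * params.v_in * mesh.chamber.height / params.viscosity
    return VelocityField(u=u, p=p, reynolds=re, diagnostics={
        "divergence_residual": float(div_res),
        "inflow_flux": inflow, "outflow_flux": outflow,
        "flux_imbalance_rel": abs(inflow + outflow) / max(abs(inflow), 1e-300),
    })


def flux_through(mesh: Mesh, u: np.ndarray, tag: int) -> float:
    """Signed volumetric flux ∮ u·n dΓ (per unit depth) through a tagged boundary.

    Outward normal: -x at the inlet, +x at the outlet (so inflow is negative).
    """
    sel = mesh.boundary_tag == tag
    edges = mesh.boundary_edges[sel]
    nx = -1.0 if tag == INLET else 1.0
    ones = np.ones(mesh.n_nodes)
    return nx * fem.boundary_product_integral(mesh.points, edges, u[:, 0], ones)
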