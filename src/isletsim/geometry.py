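"""Perifusion-chamber geometry and unstructured mesh generation.

The domain is a planar 2D cross-section of the perifusion tube: a rectangle
(flow from left to right) containing one or more circular islets, each
optionally surrounded by a concentric hydrogel capsule annulus.  Meshes are
conforming triangulations built from a graded point cloud (concentric rings
on and around each islet, a jittered hexagonal background lattice in the
lumen) triangulated with Delaunay; every element carries a subdomain tag
(lumen / tissue / capsule) and exterior edges carry inlet / outlet / wall
tags.

A 1D radial grid type is also provided for the reduced spherically-symmetric
single-islet model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "LUMEN", "TISSUE", "CAPSULE", "INLET", "OUTLET", "WALL",
    "IsletSpec", "ChamberSpec", "Geometry", "Mesh", "RadialMesh",
    "build_chamber", "mesh_geometry", "radial_grid",
]

# Subdomain codes (per element)
LUMEN, TISSUE, CAPSULE = 0, 1, 2
# Exterior boundary codes (per boundary edge)
INLET, OUTLET, WALL = 1, 2, 3


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class IsletSpec:
    """A circular islet, optionally with a concentric capsule annulus."""

    center: tuple[float, float]
    diameter: float
    encapsulated: bool = False
    capsule_thickness: float = 150e-6

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def outer_radius(self) -> float:
        """Radius of the outermost solid boundary (capsule if present)."""
        return self.radius + (self.capsule_thickness if self.encapsulated else 0.0)

    def validate(self, index: int = 0) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"islet {index}: diameter must be > 0, got {self.diameter}")
        if self.encapsulated and self.capsule_thickness <= 0:
            raise GeometryError(f"islet {index}: capsule_thickness must be > 0")


@dataclass(frozen=True)
class ChamberSpec:
    """Rectangular perifusion chamber [0, length] x [0, height] with islets."""

    length: float = 12e-3
    height: float = 4e-3
    islets: tuple[IsletSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "islets", tuple(self.islets))

    def validate(self) -> None:
        if self.length <= 0 or self.height <= 0:
            raise GeometryError("chamber length and height must be > 0")
        for i, isl in enumerate(self.islets):
            isl.validate(i)
            x, y = isl.center
            r = isl.outer_radius
            if not (r < x < self.length - r and r < y < self.height - r):
                raise GeometryError(
                    f"islet {i} (center {isl.center}, outer radius {r:.3e}) "
                    "extends outside the chamber")
        for i in range(len(self.islets)):
            for j in range(i + 1, len(self.islets)):
                a, b = self.islets[i], self.islets[j]
                d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
                if d < a.outer_radius + b.outer_radius:
                    raise GeometryError(f"islets {i} and {j} overlap")


@dataclass(frozen=True)
class Geometry:
    """Validated chamber geometry ready for meshing."""

    chamber: ChamberSpec

    @property
    def subdomain_kinds(self) -> set[int]:
        kinds = {LUMEN}
        for isl in self.chamber.islets:
            kinds.add(TISSUE)
            if isl.encapsulated:
                kinds.add(CAPSULE)
        return kinds


def build_chamber(spec: ChamberSpec) -> Geometry:
    """Validate a chamber specification and return a meshable geometry."""
    spec.validate()
    return Geometry(chamber=spec)


@dataclass
class Mesh:
    """Conforming triangulation with subdomain and boundary labels.

    points : (N, 2) node coordinates [m]
    triangles : (M, 3) node indices
    subdomain : (M,) element tags in {LUMEN, TISSUE, CAPSULE}
    islet_index : (M,) owning islet per element (-1 for lumen)
    boundary_edges : (E, 2) node pairs on the exterior boundary
    boundary_tag : (E,) tags in {INLET, OUTLET, WALL}
    """

    points: np.ndarray
    triangles: np.ndarray
    subdomain: np.ndarray
    islet_index: np.ndarray
    boundary_edges: np.ndarray
    boundary_tag: np.ndarray
    resolution: float
    chamber: ChamberSpec

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def subdomain_area(self, tag: int) -> float:
        return float(self.element_areas()[self.subdomain == tag].sum())

    def nodes_in_subdomain(self, tag: int) -> np.ndarray:
        """Indices of nodes touching at least one element of the given subdomain."""
        return np.unique(self.triangles[self.subdomain == tag])

    def boundary_nodes(self, tag: int) -> np.ndarray:
        return np.unique(self.boundary_edges[self.boundary_tag == tag])


def _ring(center, r, spacing, phase=0.0):
    m = max(8, int(round(2.0 * np.pi * r / spacing)))
    th = 2.0 * np.pi * (np.arange(m) + phase) / m
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def _islet_points(isl: IsletSpec, h_coarse: float):
    """Concentric point rings: islet interior, capsule, and a graded blend into the lumen."""
    a = isl.radius
    h_fine = min(a / 7.0, h_coarse)
    n_in = max(4, int(round(a / h_fine)))
    dr = a / n_in
    pts = [np.array([isl.center])]
    radii_spacing = []  # (radius, local spacing) for rings at and beyond r = a
    for k in range(1, n_in + 1):
        pts.append(_ring(isl.center, k * dr, dr, phase=0.5 * (k % 2)))
    r, s = a, dr
    if isl.encapsulated:
        b = isl.outer_radius
        n_cap = max(3, int(round(isl.capsule_thickness / min(2.5 * dr, isl.capsule_thickness / 3.0))))
        ds = isl.capsule_thickness / n_cap
        for k in range(1, n_cap + 1):
            rk = a + k * ds
            pts.append(_ring(isl.center, rk, ds, phase=0.5 * (k % 2)))
        r, s = b, ds
    # graded rings blending the fine interface spacing into the coarse lumen spacing
    k = 0
    while s < h_coarse:
        s = min(s * 1.4, h_coarse)
        r = r + s
        k += 1
        pts.append(_ring(isl.center, r, s, phase=0.5 * (k % 2)))
    return np.vstack(pts), r + 0.55 * h_coarse


def mesh_geometry(geom: Geometry, resolution: float = 150e-6, seed: int = 0) -> Mesh:
    """Triangulate the chamber with elements graded toward islet interfaces.

    `resolution` is the target element edge length in the open lumen [m];
    near and inside islets the size is refined to ~1/7 of the islet radius so
    the circular interfaces are resolved.  Meshing is deterministic for a
    given (geometry, resolution, seed).
    """
    if resolution <= 0:
        raise GeometryError("resolution must be > 0")
    spec = geom.chamber
    spec.validate()
    L, H = spec.length, spec.height
    rng = np.random.default_rng(seed)
    h = resolution

    clouds, drop_radii = [], []
    for isl in spec.islets:
        pts, r_drop = _islet_points(isl, h)
        clouds.append(pts)
        drop_radii.append(r_drop)

    # jittered hexagonal background lattice in the lumen
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(dy, H - 0.4 * h, dy)
    bg = []
    for j, y in enumerate(ys):
        x0 = h * (0.5 if j % 2 else 1.0)
        xs = np.arange(x0, L - 0.4 * h, h)
        row = np.column_stack([xs, np.full_like(xs, y)])
        bg.append(row)
    bg = np.vstack(bg) if bg else np.empty((0, 2))
    if len(bg):
        bg = bg + rng.uniform(-0.15 * h, 0.15 * h, size=bg.shape)
        keep = np.ones(len(bg), dtype=bool)
        keep &= (bg[:, 0] > 0.4 * h) & (bg[:, 0] < L - 0.4 * h)
        keep &= (bg[:, 1] > 0.4 * h) & (bg[:, 1] < H - 0.4 * h)
        for isl, r_drop in zip(spec.islets, drop_radii):
            d = np.hypot(bg[:, 0] - isl.center[0], bg[:, 1] - isl.center[1])
            keep &= d > r_drop
        bg = bg[keep]

    # filter islet blend rings that leak outside the chamber
    if clouds:
        cloud = np.vstack(clouds)
        inside = ((cloud[:, 0] > 0.4 * h) & (cloud[:, 0] < L - 0.4 * h)
                  & (cloud[:, 1] > 0.4 * h) & (cloud[:, 1] < H - 0.4 * h))
        cloud = cloud[inside]
    else:
        cloud = np.empty((0, 2))

    # exterior boundary, corners included
    nx = max(2, int(round(L / h)))
    ny = max(2, int(round(H / h)))
    xe = np.linspace(0.0, L, nx + 1)
    ye = np.linspace(0.0, H, ny + 1)
    bottom = np.column_stack([xe, np.zeros_like(xe)])
    top = np.column_stack([xe, np.full_like(xe, H)])
    left = np.column_stack([np.zeros(ny - 1), ye[1:-1]])
    right = np.column_stack([np.full(ny - 1, L), ye[1:-1]])

    points = np.vstack([bottom, top, left, right, cloud, bg])
    tri = Delaunay(points)
    triangles = tri.simplices.copy()

    # drop degenerate slivers (co-linear boundary points)
    p = points[triangles]
    areas = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                         - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    triangles = triangles[areas > 1e-6 * h * h]

    centroids = points[triangles].mean(axis=1)
    subdomain = np.zeros(len(triangles), dtype=np.int8)
    islet_index = np.full(len(triangles), -1, dtype=np.int32)
    for i, isl in enumerate(spec.islets):
        d = np.hypot(centroids[:, 0] - isl.center[0], centroids[:, 1] - isl.center[1])
        in_tissue = d < isl.radius
        subdomain[in_tissue] = TISSUE
        islet_index[in_tissue] = i
        if isl.encapsulated:
            in_cap = (d >= isl.radius) & (d < isl.outer_radius)
            subdomain[in_cap] = CAPSULE
            islet_index[in_cap] = i

    edges, tags = _exterior_edges(points, triangles, L, H)
    return Mesh(points=points, triangles=triangles, subdomain=subdomain,
                islet_index=islet_index, boundary_edges=edges, boundary_tag=tags,
                resolution=resolution, chamber=spec)


def _exterior_edges(points, triangles, L, H):
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    _, idx, counts = np.unique(e_sorted, axis=0, return_index=True, return_counts=True)
    ext = e_sorted[idx[counts == 1]]
    mids = 0.5 * (points[ext[:, 0]] + points[ext[:, 1]])
    tol = 1e-9 * max(L, H)
    tags = np.full(len(ext), WALL, dtype=np.int8)
    tags[np.abs(mids[:, 0]) < tol] = INLET
    tags[np.abs(mids[:, 0] - L) < tol] = OUTLET
    return ext, tags


@dataclass(frozen=True)
class RadialMesh:
    """1D radial grid for the spherically-symmetric single-islet model.

    radii : strictly increasing node radii on [0, r_outer], including r = 0,
        the islet surface, and (if present) the capsule outer surface.
    """

    radii: np.ndarray
    islet_radius: float
    capsule_radius: float | None = None

    @property
    def r_outer(self) -> float:
        return float(self.radii[-1])

    def region_of(self, r_mid: np.ndarray) -> np.ndarray:
        """Subdomain code for interval midpoints."""
        reg = np.full(r_mid.shape, LUMEN, dtype=np.int8)
        reg[r_mid < self.islet_radius] = TISSUE
        if self.capsule_radius is not None:
            reg[(r_mid >= self.islet_radius) & (r_mid < self.capsule_radius)] = CAPSULE
        return reg


def radial_grid(islet_diameter: float, medium_shell: float,
                capsule: float | None = None, n_nodes: int = 100) -> RadialMesh:
    """Graded 1D radial grid: islet core, optional capsule shell, medium shell.

    Nodes cluster toward the material interfaces (cosine spacing within each
    region); interface radii are grid nodes exactly.
    """
    if islet_diameter <= 0:
        raise GeometryError("islet_diameter must be > 0")
    if medium_shell <= 0:
        raise GeometryError("medium_shell must be > 0")
    if n_nodes < 20:
        raise GeometryError("n_nodes must be >= 20")
    a = 0.5 * islet_diameter
    bounds = [0.0, a]
    if capsule is not None:
        if capsule <= 0:
            raise GeometryError("capsule thickness must be > 0")
        bounds.append(a + capsule)
    bounds.append(bounds[-1] + medium_shell)
    bounds = np.asarray(bounds)
    lengths = np.diff(bounds)
    # allocate interval counts proportional to sqrt(length), at least 6 per region
    w = np.sqrt(lengths)
    n_int = n_nodes - 1
    counts = np.maximum(6, np.floor(n_int * w / w.sum()).astype(int))
    while counts.sum() > n_int:
        counts[np.argmax(counts)] -= 1
    counts[np.argmax(lengths)] += n_int - counts.sum()
    radii = [np.array([0.0])]
    for (lo, hi), m in zip(zip(bounds[:-1], bounds[1:]), counts):
        t = 0.5 * (1.0 - np.cos(np.pi * np.linspace(0.0, 1.0, m + 1)))
        radii.append(lo + (hi - lo) * t[1:])
    radii = np.concatenate(radii)
    return RadialMesh(radii=radii, islet_radius=a,
                      capsule_radius=(a + capsule) if capsule is not None else None)
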