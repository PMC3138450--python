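"""Minimal legacy-VTK (ASCII) export of mesh-based field snapshots."""

from __future__ import annotations

import numpy as np

from .geometry import Mesh

__all__ = ["write_vtk"]


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an unstructured-grid .vtk file with optional nodal/element scalars."""
    pts, tris = mesh.points, mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nisletsim snapshot\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            fh.write(f"{x:.9e} {y:.9e} 0.0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("\n".join(["5"] * len(tris)) + "\n")
        cell_data = dict(cell_data or {})
        cell_data.setdefault("subdomain", mesh.subdomain.astype(float))
        if point_data:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9e} {v[1]:.9e} 0.0\n")
        fh.write(f"CELL_DATA {len(tris)}\n")
        for name, arr in cell_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{float(v):.9e}" for v in arr) + "\n")
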