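"""Mesh and field I/O.

Writes legacy-VTK ASCII unstructured grids (tet meshes with point/cell
data: extent of infarction, fibre vectors, region labels, displacements)
readable by ParaView, and reads/writes Gmsh v2.2 ASCII meshes for
user-supplied LV geometries.  Only the small subset of each format that
the package produces/consumes is implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk", "read_gmsh", "write_gmsh"]


def write_vtk(path, points: np.ndarray, tets: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None,
              title: str = "cardioib output") -> None:
    """Write a tetrahedral mesh with optional data arrays (legacy VTK ASCII)."""
    points = np.asarray(points, float)
    tets = np.asarray(tets, int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        for t in tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        fh.write("\n".join(["10"] * len(tets)) + "\n")
        for label, data, n in (("POINT_DATA", point_data, len(points)),
                               ("CELL_DATA", cell_data, len(tets))):
            if not data:
                continue
            fh.write(f"{label} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr.astype(float)) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")


def write_gmsh(path, points: np.ndarray, tets: np.ndarray) -> None:
    """Write a Gmsh v2.2 ASCII mesh (tets only, single physical group)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{len(points)}\n")
        for i, p in enumerate(points, 1):
            fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"$EndNodes\n$Elements\n{len(tets)}\n")
        for i, t in enumerate(tets, 1):
            fh.write(f"{i} 4 2 1 1 {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")
        fh.write("$EndElements\n")


def read_gmsh(path):
    """Read nodes and tetrahedra from a Gmsh v2.2 ASCII mesh.

    Returns (points, tets) with 0-based connectivity; other element
    types are ignored.
    """
    points, tets = [], []
    node_ids = {}
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            tag = line.strip()
            if tag == "$Nodes":
                n = int(next(lines))
                for _ in range(n):
                    parts = next(lines).split()
                    node_ids[int(parts[0])] = len(points)
                    points.append([float(x) for x in parts[1:4]])
            elif tag == "$Elements":
                n = int(next(lines))
                for _ in range(n):
                    parts = next(lines).split()
                    if int(parts[1]) == 4:          # 4-node tetrahedron
                        ntags = int(parts[2])
                        conn = [node_ids[int(x)] for x in parts[3 + ntags:7 + ntags]]
                        tets.append(conn)
    if not points:
        raise ValueError(f"no nodes found in {path}")
    return np.asarray(points), np.asarray(tets, int)
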