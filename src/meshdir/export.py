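"""Plain-text mesh export: VTK legacy unstructured grid and TetGen node/ele."""
from __future__ import annotations

from pathlib import Path

from .meshing import TetMesh


def write_vtk(mesh: TetMesh, path: str) -> None:
    """ASCII VTK legacy unstructured-grid file with a corner-flag scalar."""
    p = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.10g}" for c in v) for v in mesh.vertices]
    t = mesh.tets
    lines.append(f"CELLS {len(t)} {5 * len(t)}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in t]
    lines.append(f"CELL_TYPES {len(t)}")
    lines += ["10"] * len(t)
    lines.append(f"POINT_DATA {mesh.n_vertices}")
    lines.append("SCALARS is_corner int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(f)) for f in mesh.is_corner]
    p.write_text("\n".join(lines) + "\n")


def read_vtk(path: str) -> TetMesh:
    """Read back an ASCII VTK legacy tetrahedral mesh written by write_vtk."""
    import numpy as np

    lines = Path(path).read_text().splitlines()
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n_pts = int(lines[i].split()[1])
    verts = np.array([[float(x) for x in ln.split()]
                      for ln in lines[i + 1: i + 1 + n_pts]])
    j = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
    n_cells = int(lines[j].split()[1])
    tets = np.array([[int(x) for x in ln.split()[1:]]
                     for ln in lines[j + 1: j + 1 + n_cells]])
    try:
        s = next(k for k, ln in enumerate(lines)
                 if ln.startswith("LOOKUP_TABLE"))
        flags = np.array([int(ln) for ln in lines[s + 1: s + 1 + n_pts]],
                         dtype=bool)
    except StopIteration:
        flags = np.zeros(n_pts, dtype=bool)
    return TetMesh(verts, tets, flags)


def write_tetgen(mesh: TetMesh, stem: str) -> None:
    """TetGen .node/.ele pair (1-based indices)."""
    node = [f"{mesh.n_vertices} 3 0 1"]
    node += [
        f"{i + 1} " + " ".join(f"{c:.10g}" for c in v) + f" {int(mesh.is_corner[i])}"
        for i, v in enumerate(mesh.vertices)
    ]
    Path(f"{stem}.node").write_text("\n".join(node) + "\n")
    ele = [f"{len(mesh.tets)} 4 0"]
    ele += [
        f"{i + 1} " + " ".join(str(j + 1) for j in tet)
        for i, tet in enumerate(mesh.tets)
    ]
    Path(f"{stem}.ele").write_text("\n".join(ele) + "\n")
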