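"""Diffusing the vertex DVF to voxels and warping the planning volume.

A displacement vector is stored at each mesh vertex (the optimization
unknowns D); every voxel center receives the barycentric combination of the
four vertex displacements of its containing tetrahedron, giving a piecewise
linear, continuous voxel field Dv.  The deformed image is produced by pull
(backward) mapping: U_new(a,b,c) = U_original(a + Dv1, b + Dv2, c + Dv3)
with trilinear resampling and zero background outside the raster.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .interp import trilinear
from .meshing import TetMesh
from .volume import Volume


@dataclass
class BarycentricAssignment:
    """Voxel/point -> tetrahedron assignment with interpolation weights.

    ``weights_matrix`` is a sparse (n_points, n_vertices) operator W with
    four entries per row; the voxel displacement field is W @ D.
    """

    tet_ids: np.ndarray  # (n_points,)
    weights_matrix: sparse.csr_matrix

    def interpolate(self, vertex_values: np.ndarray) -> np.ndarray:
        return self.weights_matrix @ vertex_values


def _tet_inverses(mesh: TetMesh) -> np.ndarray:
    v = mesh.vertices
    t = mesh.tets
    e = np.stack([v[t[:, 1]] - v[t[:, 0]],
                  v[t[:, 2]] - v[t[:, 0]],
                  v[t[:, 3]] - v[t[:, 0]]], axis=-1)  # (T, 3, 3) columns
    return np.linalg.inv(e)


def locate_points(points: np.ndarray, mesh: TetMesh,
                  tol: float = 1e-9) -> BarycentricAssignment:
    """Assign each point to a containing tetrahedron with barycentric weights.

    Tetrahedra are swept in id order and each point is claimed by the first
    tet containing it (ties on shared faces therefore resolve to the lowest
    tet id).  Weights as small as ``-tol`` are accepted and clipped to absorb
    floating-point noise on faces; a second, looser pass (1e-6) catches
    points sitting exactly on the hull.  Points outside the mesh raise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n_pts = len(pts)
    inv = _tet_inverses(mesh)
    v0 = mesh.vertices[mesh.tets[:, 0]]
    tet_ids = np.full(n_pts, -1, dtype=np.intp)
    bary = np.zeros((n_pts, 4))

    lo = np.min(mesh.vertices[mesh.tets], axis=1)  # (T, 3)
    hi = np.max(mesh.vertices[mesh.tets], axis=1)

    for pass_tol in (tol, 1e-6):
        unassigned = tet_ids < 0
        if not np.any(unassigned):
            break
        for t in range(len(mesh.tets)):
            cand = np.flatnonzero(unassigned)
            if len(cand) == 0:
                break
            p = pts[cand]
            inside_box = np.all((p >= lo[t] - pass_tol) & (p <= hi[t] + pass_tol),
                                axis=1)
            cand = cand[inside_box]
            if len(cand) == 0:
                continue
            lam = (pts[cand] - v0[t]) @ inv[t].T
            w0 = 1.0 - lam.sum(axis=1)
            w = np.column_stack([w0, lam])
            ok = np.all(w >= -pass_tol, axis=1)
            hit = cand[ok]
            tet_ids[hit] = t
            bary[hit] = np.clip(w[ok], 0.0, None)
            unassigned[hit] = False
    if np.any(tet_ids < 0):
        n_bad = int(np.sum(tet_ids < 0))
        raise ValueError(f"{n_bad} points lie outside the mesh hull")

    bary /= bary.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n_pts), 4)
    cols = mesh.tets[tet_ids].ravel()
    w_mat = sparse.csr_matrix(
        (bary.ravel(), (rows, cols)), shape=(n_pts, mesh.n_vertices)
    )
    return BarycentricAssignment(tet_ids, w_mat)


def locate_and_barycentric(point, mesh: TetMesh):
    """Single-point convenience wrapper: returns (tet id, 4 weights)."""
    assign = locate_points(np.asarray(point, dtype=float).reshape(1, 3), mesh)
    t = int(assign.tet_ids[0])
    verts = mesh.tets[t]
    w = np.array(assign.weights_matrix[0, verts].todense()).ravel()
    return t, w


def grid_assignment(mesh: TetMesh, shape,
                    points: np.ndarray | None = None) -> BarycentricAssignment:
    """Barycentric assignment for every voxel center of a raster.

    Exploits the regular grid: each tet only examines the integer-index
    subgrid inside its bounding box, swept in tet-id order so shared-face
    ties resolve to the lowest id.  ``points`` overrides the default integer
    centers with an (nx, ny, nz, 3) array of arbitrary grid-sample
    coordinates on the same lattice topology (used by multiresolution).
    """
    nx, ny, nz = (int(s) for s in shape)
    if points is not None:
        pts3d = np.asarray(points, dtype=float)
    else:
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        pts3d = np.stack([ii, jj, kk], axis=-1).astype(float)
    if points is not None:
        # irregular sample coordinates: fall back to the generic locator
        return locate_points(pts3d.reshape(-1, 3), mesh)

    n_pts = nx * ny * nz
    inv = _tet_inverses(mesh)
    v0 = mesh.vertices[mesh.tets[:, 0]]
    tet_ids = np.full(n_pts, -1, dtype=np.intp)
    bary = np.zeros((n_pts, 4))
    lo = np.min(mesh.vertices[mesh.tets], axis=1)
    hi = np.max(mesh.vertices[mesh.tets], axis=1)
    shape_arr = np.array([nx, ny, nz])

    for pass_tol in (1e-9, 1e-6):
        lo_i = np.maximum(np.ceil(lo - pass_tol).astype(int), 0)
        hi_i = np.minimum(np.floor(hi + pass_tol).astype(int), shape_arr - 1)
        for t in range(len(mesh.tets)):
            if np.any(hi_i[t] < lo_i[t]):
                continue
            xs = np.arange(lo_i[t, 0], hi_i[t, 0] + 1)
            ys = np.arange(lo_i[t, 1], hi_i[t, 1] + 1)
            zs = np.arange(lo_i[t, 2], hi_i[t, 2] + 1)
            gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
            flat = (gx.ravel() * ny + gy.ravel()) * nz + gz.ravel()
            flat = flat[tet_ids[flat] < 0]
            if len(flat) == 0:
                continue
            p = np.column_stack([flat // (ny * nz), (flat // nz) % ny, flat % nz])
            lam = (p.astype(float) - v0[t]) @ inv[t].T
            w0 = 1.0 - lam.sum(axis=1)
            w = np.column_stack([w0, lam])
            ok = np.all(w >= -pass_tol, axis=1)
            hit = flat[ok]
            tet_ids[hit] = t
            bary[hit] = np.clip(w[ok], 0.0, None)
        if np.all(tet_ids >= 0):
            break
    if np.any(tet_ids < 0):
        raise ValueError(
            f"{int(np.sum(tet_ids < 0))} voxel centers not covered by the mesh"
        )
    bary /= bary.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n_pts), 4)
    cols = mesh.tets[tet_ids].ravel()
    w_mat = sparse.csr_matrix(
        (bary.ravel(), (rows, cols)), shape=(n_pts, mesh.n_vertices)
    )
    return BarycentricAssignment(tet_ids, w_mat)


def interpolate_dvf(mesh: TetMesh, displacements: np.ndarray, shape,
                    assignment: BarycentricAssignment | None = None):
    """Vertex DVF -> voxel DVF (three 3D component arrays, voxel units)."""
    if assignment is None:
        assignment = grid_assignment(mesh, shape)
    dv = assignment.interpolate(np.asarray(displacements, dtype=float))
    shape = tuple(int(s) for s in shape)
    return tuple(dv[:, d].reshape(shape) for d in range(3))


def warp_image(u_original: Volume, dv) -> Volume:
    """Apply a voxel displacement field by backward trilinear sampling."""
    d1, d2, d3 = (np.asarray(c, dtype=float) for c in dv)
    if d1.shape != u_original.shape:
        raise ValueError("DVF shape does not match the volume")
    nx, ny, nz = u_original.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pulled = np.stack([ii + d1, jj + d2, kk + d3], axis=-1)
    out = trilinear(u_original.data, pulled)
    return Volume(out, spacing=u_original.spacing, origin=u_original.origin)
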