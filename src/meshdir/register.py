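"""Intensity-based 3D-2D deformable registration on the tetrahedral mesh.

The unknowns are the per-vertex displacements D (voxel units of the
original grid, pull convention).  The objective is

    E(D) = mu * L(D) + sum_m || R(D, theta_m) - I(theta_m) ||^2

where R is the DRR of the warped volume (sparse projection matrix applied
to U_new(D)), I are the measured line-integral projections, and L is the
squared graph-Laplacian smoothness penalty over the mesh one-ring
neighborhoods, summed over every vertex except those on the external
border (the bounding-box corners), whose displacements still enter as
neighbors:

    L(D) = sum_{i interior} sum_{d=1..3}
           ( sum_{j in N(i)} (D_d(j) - D_d(i)) / |N(i)| )^2.

The similarity gradient is assembled analytically by the chain rule:
back-projection of the residual gives dE_sim/dU_new per voxel, the exact
derivative of the trilinear interpolant of U_original at the pulled
position gives dU_new/dDv, and the barycentric weights distribute voxel
contributions to vertices.  L-BFGS minimizes E; the weighting mu defaults
to 10.0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize

from .deform import BarycentricAssignment, grid_assignment
from .interp import trilinear_grad
from .meshing import TetMesh
from .project import ConeBeamGeometry, ProjectionImage, siddon_weights
from .volume import Volume

DEFAULT_MU = 10.0


@dataclass
class MeshGraph:
    """One-ring adjacency of the tet mesh with external-border flags."""

    n_vertices: int
    neighbors: list[np.ndarray]
    is_border: np.ndarray
    _B: sparse.csr_matrix | None = None  # interior-row Laplacian operator

    @classmethod
    def from_mesh(cls, mesh: TetMesh, freeze_corners_as_border: bool = True):
        edges = mesh.edges()
        adj: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        neighbors = [np.array(sorted(s), dtype=np.intp) for s in adj]
        border = mesh.is_corner.copy() if freeze_corners_as_border else \
            np.zeros(mesh.n_vertices, dtype=bool)
        return cls(mesh.n_vertices, neighbors, border)

    @property
    def laplacian_operator(self) -> sparse.csr_matrix:
        """Sparse B with one row per interior vertex: (B D)_i = mean_j D_j - D_i."""
        if self._B is None:
            rows, cols, vals = [], [], []
            r = 0
            for i in range(self.n_vertices):
                if self.is_border[i]:
                    continue
                nb = self.neighbors[i]
                if len(nb) == 0:
                    continue
                w = 1.0 / len(nb)
                rows.extend([r] * (len(nb) + 1))
                cols.extend(list(nb) + [i])
                vals.extend([w] * len(nb) + [-1.0])
                r += 1
            self._B = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(r, self.n_vertices)
            )
        return self._B


def laplacian_energy_grad(displacements: np.ndarray, graph: MeshGraph):
    """L(D) and its analytic gradient (both w.r.t. all vertex rows)."""
    d = np.asarray(displacements, dtype=float)
    B = graph.laplacian_operator
    r = B @ d  # (n_interior, 3)
    energy = float(np.sum(r * r))
    grad = 2.0 * (B.T @ r)
    return energy, grad


@dataclass
class EnergyBreakdown:
    total: list = field(default_factory=list)
    regularization: list = field(default_factory=list)
    similarity: list = field(default_factory=list)

    def append(self, e_reg: float, e_sim: float) -> None:
        self.regularization.append(e_reg)
        self.similarity.append(e_sim)
        self.total.append(e_reg + e_sim)


class _SimilarityModel:
    """Precomputed operators for one resolution level.

    Caches the sparse projection matrices (one per angle), the barycentric
    weight operator W at the level's sample points, and the mapping between
    original-grid index coordinates (in which D lives) and the level grid.
    """

    def __init__(self, u_level: Volume, geoms: list[ConeBeamGeometry],
                 measured: list[np.ndarray], mesh: TetMesh,
                 vol_scale: int = 1,
                 assignment: BarycentricAssignment | None = None):
        self.u = u_level
        self.geoms = geoms
        self.measured = [np.asarray(m, dtype=float).ravel() for m in measured]
        self.scale = float(vol_scale)
        self.offset = (vol_scale - 1) / 2.0
        shape = u_level.shape
        nx, ny, nz = shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        # level voxel centers expressed in original-grid index coordinates
        self.centers_orig = (
            np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * self.scale
            + self.offset
        )
        if assignment is None:
            if vol_scale == 1:
                assignment = grid_assignment(mesh, shape)
            else:
                from .deform import locate_points
                assignment = locate_points(self.centers_orig, mesh)
        self.assignment = assignment
        self.W = assignment.weights_matrix
        self.P = [siddon_weights(u_level, g) for g in geoms]

    def energy_grad(self, displacements: np.ndarray):
        """E_sim and dE_sim/dD for the current vertex displacements."""
        dv = self.W @ displacements  # (n_vox, 3) in original voxel units
        q_level = (self.centers_orig + dv - self.offset) / self.scale
        u_new, g = trilinear_grad(self.u.data, q_level)
        e_sim = 0.0
        back = np.zeros_like(u_new)
        for p_mat, meas in zip(self.P, self.measured):
            r = p_mat @ u_new - meas
            e_sim += float(r @ r)
            back += 2.0 * (p_mat.T @ r)
        # chain rule: dU_new/dD_d = dU/dq_d * (1/scale) * w_i
        s = back[:, None] * g / self.scale  # (n_vox, 3)
        grad = self.W.T @ s
        return e_sim, grad, u_new


def similarity_energy_grad(displacements, mesh: TetMesh, u_original: Volume,
                           projections: list, geoms: list[ConeBeamGeometry],
                           assignment: BarycentricAssignment | None = None):
    """One-shot E_sim and gradient at full resolution (operator not cached)."""
    measured = [p.pixels if isinstance(p, ProjectionImage) else p
                for p in projections]
    if len(measured) != len(geoms):
        raise ValueError("number of projections and geometries differ")
    model = _SimilarityModel(u_original, geoms, measured, mesh,
                             assignment=assignment)
    e, g, _ = model.energy_grad(np.asarray(displacements, dtype=float))
    return e, g


def register(u_original: Volume, projections: list, geoms: list,
             mesh: TetMesh, mu: float = DEFAULT_MU, max_iter: int = 100,
             d_init: np.ndarray | None = None,
             graph: MeshGraph | None = None,
             freeze_corners: bool = False,
             gtol: float = 1e-6,
             vol_scale: int = 1):
    """Minimize the registration energy over the vertex DVF with L-BFGS.

    Returns ``(D, EnergyBreakdown)``.  ``projections`` are measured
    line-integral images (arrays or :class:`ProjectionImage`) matching
    ``geoms`` one-to-one and the resolution of ``u_original`` after
    ``vol_scale`` downsampling.
    """
    measured = [p.pixels if isinstance(p, ProjectionImage) else np.asarray(p)
                for p in projections]
    if len(measured) != len(geoms):
        raise ValueError("number of projections and geometries differ")
    u_level = u_original.downsample(vol_scale) if vol_scale > 1 else u_original
    model = _SimilarityModel(u_level, geoms, measured, mesh,
                             vol_scale=vol_scale)
    if graph is None:
        graph = MeshGraph.from_mesh(mesh)
    n = mesh.n_vertices
    d0 = np.zeros((n, 3)) if d_init is None else \
        np.array(d_init, dtype=float).reshape(n, 3)
    free = ~mesh.is_corner if freeze_corners else np.ones(n, dtype=bool)
    history = EnergyBreakdown()
    frozen_rows = d0[~free]

    def fun(x):
        d = d0.copy()
        d[free] = x.reshape(-1, 3)
        e_reg, g_reg = laplacian_energy_grad(d, graph)
        e_sim, g_sim, _ = model.energy_grad(d)
        e = mu * e_reg + e_sim
        if not np.isfinite(e):
            raise FloatingPointError("non-finite registration energy")
        g = mu * g_reg + g_sim
        fun.last = (mu * e_reg, e_sim)
        return e, g[free].ravel()

    def cb(xk):
        history.append(*fun.last)

    e0, _ = fun(d0[free].ravel())
    history.append(*fun.last)
    res = minimize(fun, d0[free].ravel(), jac=True, method="L-BFGS-B",
                   callback=cb,
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14,
                            "maxcor": 10})
    d = d0.copy()
    d[free] = res.x.reshape(-1, 3)
    d[~free] = frozen_rows
    return d, history


def _downsample_projection(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(img, dtype=float)
    from skimage.measure import block_reduce

    a = np.asarray(img, dtype=float)
    n = [s - s % factor for s in a.shape]
    return block_reduce(a[: n[0], : n[1]], (factor, factor), np.mean)


def _coarsen_geometry(g: ConeBeamGeometry, factor: int) -> ConeBeamGeometry:
    if factor == 1:
        return g
    return ConeBeamGeometry(
        angle_deg=g.angle_deg, sad_mm=g.sad_mm, sdd_mm=g.sdd_mm,
        det_shape=(g.det_shape[0] // factor, g.det_shape[1] // factor),
        pixel_pitch_mm=g.pixel_pitch_mm * factor,
        isocenter_mm=g.isocenter_mm,
    )


DEFAULT_SCHEDULE = [(4, 4, 30), (2, 2, 15), (1, 1, 5)]


def multires_register(u_original: Volume, projections: list, geoms: list,
                      mesh: TetMesh, schedule=None, mu: float = DEFAULT_MU,
                      d_init: np.ndarray | None = None,
                      freeze_corners: bool = False):
    """Coarse-to-fine registration.

    ``schedule`` is a list of (volume scale, projection scale, iterations),
    coarsest first; the default mirrors the 30/15/5 iteration pattern over
    three levels.  The vertex DVF is resolution independent, so it passes
    unchanged between levels as a warm start.  Returns (D, list of
    per-level histories).
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    measured = [p.pixels if isinstance(p, ProjectionImage) else np.asarray(p)
                for p in projections]
    d = d_init
    histories = []
    for vol_scale, proj_scale, iters in schedule:
        if any(s // vol_scale < 8 for s in u_original.shape):
            raise ValueError(f"volume scale {vol_scale} yields a dimension < 8")
        geoms_l = [_coarsen_geometry(g, proj_scale) for g in geoms]
        meas_l = [_downsample_projection(m, proj_scale) for m in measured]
        d, hist = register(u_original, meas_l, geoms_l, mesh, mu=mu,
                           max_iter=iters, d_init=d,
                           freeze_corners=freeze_corners, vol_scale=vol_scale)
        histories.append(hist)
    return d, histories
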