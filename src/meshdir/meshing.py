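"""Particle-based adaptive tetrahedral mesh generation.

Mesh vertices are treated as mutually repelling particles.  An isotropic
metric M(v) = rho(v)^(2/3) * I (m = 3 spatial dimensions) warps distances so
that a uniform particle distribution under the metric becomes an adaptive
distribution in the volume: spacing shrinks where the density rho is large
(near image features).  The pair energy between particles i, j is

    E_ij = exp(-(v_i - v_j)^T M_ij (v_i - v_j) / (4 sigma^2)),

with M_ij the average of the metric at the two positions and sigma a global
Gaussian kernel width sigma = 0.3 * (Omega_bar / N_v)^(1/3), Omega_bar being
the density-weighted volume (the measure of the domain in the embedding
space).  L-BFGS minimizes the total energy with interactions truncated to a
5-sigma neighborhood; Delaunay tetrahedralization of the optimized particles
plus the 8 bounding-box corners yields the mesh.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import Delaunay, cKDTree

from .features import BinaryMask, DensityField
from .interp import trilinear


@dataclass
class MetricTensorField:
    """Scalar isotropic metric M(v) = rho(v)^(2/3) * I sampled from a raster.

    ``rho13_at`` trilinearly samples rho^(1/3); the scalar metric coefficient
    is its square.  A uniform field (rho = 1) is the default.
    """

    rho_cuberoot: np.ndarray | None = None

    def rho13_at(self, pts: np.ndarray) -> np.ndarray:
        if self.rho_cuberoot is None:
            return np.ones(np.asarray(pts).shape[:-1])
        # clamp sampling inside the raster; the field is defined on the grid
        shape = np.array(self.rho_cuberoot.shape, dtype=float)
        p = np.clip(np.asarray(pts, dtype=float), 0.0, shape - 1.0)
        return np.maximum(trilinear(self.rho_cuberoot, p), 1.0)

    def metric_at(self, pts: np.ndarray) -> np.ndarray:
        """Scalar coefficient of M(v): rho^(2/3)."""
        return self.rho13_at(pts) ** 2

    @property
    def rho13_min(self) -> float:
        if self.rho_cuberoot is None:
            return 1.0
        return float(max(np.min(self.rho_cuberoot), 1.0))

    @classmethod
    def from_density(cls, density: DensityField) -> "MetricTensorField":
        return cls(rho_cuberoot=density.rho_cuberoot)


@dataclass
class ParticleSet:
    positions: np.ndarray  # (N_v, 3) voxel coordinates
    sigma: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.positions) < 1:
            raise ValueError("need at least 1 particle")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class TetMesh:
    vertices: np.ndarray  # (N_v + 8, 3)
    tets: np.ndarray  # (T, 4) int
    is_corner: np.ndarray  # (N_v + 8,) bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.intp)
        self.is_corner = np.asarray(self.is_corner, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the tetrahedralization."""
        t = self.tets
        pairs = np.vstack(
            [t[:, [a, b]] for a, b in
             ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
        )
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)


def embedding_measure(density: DensityField | None, mask: BinaryMask | None,
                      shape=None) -> float:
    """Omega_bar: density-weighted volume (sum of rho over domain voxels)."""
    if density is None:
        if mask is not None:
            return float(np.count_nonzero(mask.data))
        return float(np.prod(shape))
    rho = density.rho
    if mask is not None:
        rho = rho[mask.data]
    return float(np.sum(rho))


def kernel_width(volume_measure: float, n_particles: int) -> float:
    """sigma = 0.3 * (embedding volume per particle)^(1/3)."""
    if volume_measure <= 0 or n_particles <= 0:
        raise ValueError("volume measure and particle count must be positive")
    return 0.3 * (volume_measure / n_particles) ** (1.0 / 3.0)


def pair_energy(v_i, v_j, metric: MetricTensorField, sigma: float) -> float:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    m_ij = 0.5 * (metric.metric_at(v_i) + metric.metric_at(v_j))
    d = v_i - v_j
    return float(np.exp(-m_ij * np.dot(d, d) / (4.0 * sigma**2)))


def pair_force(v_i, v_j, metric: MetricTensorField, sigma: float) -> np.ndarray:
    """dE_ij/dv_j with the metric frozen at the current positions.

    For the isotropic scalar metric this is M_ij (v_i - v_j) / (2 sigma^2)
    times the pair energy; it equals the numerical gradient of
    :func:`pair_energy` wherever the metric is locally constant.
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    m_ij = 0.5 * (metric.metric_at(v_i) + metric.metric_at(v_j))
    d = v_i - v_j
    e = np.exp(-m_ij * np.dot(d, d) / (4.0 * sigma**2))
    return m_ij * d / (2.0 * sigma**2) * e


def total_energy_grad(particles: ParticleSet, metric: MetricTensorField,
                      sigma: float | None = None):
    """Truncated total energy and its gradient w.r.t. all positions.

    Pairs beyond an embedding distance of 5 sigma contribute nothing; the
    neighborhood is found with a k-d tree using the conservative Euclidean
    radius 5 sigma / rho13_min (a superset of the embedding-space ball).
    Energy counts ordered pairs, as the double sum over i != j.
    """
    sigma = particles.sigma if sigma is None else sigma
    pos = particles.positions
    n = len(pos)
    grad = np.zeros_like(pos)
    if n < 2:
        return 0.0, grad
    radius = 5.0 * sigma / metric.rho13_min
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0, grad
    i, j = pairs[:, 0], pairs[:, 1]
    m = 0.5 * (metric.metric_at(pos[i]) + metric.metric_at(pos[j]))
    d = pos[i] - pos[j]
    dist2 = np.einsum("ij,ij->i", d, d)
    e = np.exp(-m * dist2 / (4.0 * sigma**2))
    energy = 2.0 * float(np.sum(e))  # ordered pairs
    # frozen-metric gradient: dE/dv_i = -(M_ij / sigma^2) d * e  (x2 ordered)
    coeff = (m * e / sigma**2)[:, None] * d
    np.subtract.at(grad, i, 2.0 * coeff)
    np.add.at(grad, j, 2.0 * coeff)
    # note: ordered-pair double counting folds the factor 2 into both rows
    grad *= 0.5
    return energy, grad


def _projector(mask: BinaryMask):
    """Return a function snapping positions to the nearest in-mask voxel center."""
    inside = mask.data
    _, (ix, iy, iz) = ndimage.distance_transform_edt(~inside, return_indices=True)

    def project(pos: np.ndarray) -> np.ndarray:
        pos = np.array(pos, dtype=float)
        idx = np.clip(np.round(pos).astype(int), 0,
                      np.array(inside.shape) - 1)
        bad = ~inside[idx[:, 0], idx[:, 1], idx[:, 2]]
        if np.any(bad):
            b = idx[bad]
            pos[bad] = np.stack(
                [ix[b[:, 0], b[:, 1], b[:, 2]],
                 iy[b[:, 0], b[:, 1], b[:, 2]],
                 iz[b[:, 0], b[:, 1], b[:, 2]]], axis=1
            ).astype(float)
        return pos

    return project


def initialize_particles(n_particles: int, metric: MetricTensorField,
                         mask: BinaryMask, seed: int = 0,
                         sigma: float | None = None) -> ParticleSet:
    """Density-proportional rejection sampling of initial particle positions."""
    rng = np.random.default_rng(seed)
    idx = np.argwhere(mask.data)
    if len(idx) < n_particles:
        raise ValueError("mask has fewer voxels than requested particles")
    rho = metric.rho13_at(idx.astype(float)) ** 3
    p = rho / rho.sum()
    chosen = rng.choice(len(idx), size=n_particles, replace=False, p=p)
    pos = idx[chosen].astype(float) + rng.uniform(-0.4, 0.4, size=(n_particles, 3))
    pos = _projector(mask)(pos)
    if sigma is None:
        sigma = kernel_width(float(rho.sum()), n_particles)
    return ParticleSet(pos, sigma)


def optimize_particles(init: ParticleSet, metric: MetricTensorField,
                       mask: BinaryMask, max_iter: int = 100,
                       tol: float = 1e-3) -> ParticleSet:
    """Quasi-Newton energy minimization with in-mask projection.

    L-BFGS runs in short bursts; after each burst every particle outside the
    body mask is snapped to the nearest in-mask voxel center.  Terminates on
    gradient norm < tol, maximal particle displacement < tol, or the
    iteration budget.
    """
    project = _projector(mask)
    pos = project(init.positions)
    sigma = init.sigma
    n = len(pos)

    def fun(x):
        ps = ParticleSet(x.reshape(n, 3), sigma)
        e, g = total_energy_grad(ps, metric)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite particle energy")
        return e, g.ravel()

    burst = 10
    done = 0
    while done < max_iter:
        it = min(burst, max_iter - done)
        res = minimize(fun, pos.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": it, "gtol": tol, "ftol": 1e-12})
        new = project(res.x.reshape(n, 3))
        moved = float(np.max(np.linalg.norm(new - pos, axis=1)))
        pos = new
        done += max(res.nit, 1)
        _, g = fun(pos.ravel())
        if np.linalg.norm(g) < tol or moved < tol:
            break
    return ParticleSet(pos, sigma)


def _orient_tets(vertices: np.ndarray, tets: np.ndarray,
                 drop_degenerate: bool = True) -> np.ndarray:
    """Consistently orient tets (positive volume); drop zero-volume slivers.

    Degenerate simplices (qhull can emit near-coplanar slivers on the hull)
    enclose no volume, so removing them cannot break voxel coverage.
    """
    v = vertices
    a, b, c, d = (v[tets[:, k]] for k in range(4))
    det = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    if drop_degenerate:
        edge = np.linalg.norm(b - a, axis=1)
        keep = np.abs(det) > 1e-9 * np.maximum(edge, 1.0) ** 3
        tets, det = tets[keep], det[keep]
    flip = det < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def bounding_box_corners(volume_shape) -> np.ndarray:
    n = np.asarray(volume_shape, dtype=float) - 1.0
    return np.array(
        [[x, y, z] for x in (0.0, n[0]) for y in (0.0, n[1]) for z in (0.0, n[2])]
    )


def build_tet_mesh(particles: ParticleSet, volume_shape) -> TetMesh:
    """Delaunay tetrahedralization of particles + 8 bounding-box corners."""
    if len(particles.positions) < 4:
        raise ValueError("mesh construction needs at least 4 particles")
    corners = bounding_box_corners(volume_shape)
    verts = np.vstack([particles.positions, corners])
    try:
        tri = Delaunay(verts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate point set for Delaunay: {exc}") from exc
    tets = _orient_tets(verts, np.asarray(tri.simplices, dtype=np.intp))
    is_corner = np.zeros(len(verts), dtype=bool)
    is_corner[len(particles.positions):] = True
    return TetMesh(verts, tets, is_corner)


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def uniform_orthogonal_mesh(n_target: int, volume_shape) -> TetMesh:
    """Regular lattice split into 6 tets per cell (Kuhn decomposition).

    The lattice spans the full bounding box, so its 8 extreme points are the
    bounding-box corners; per-axis point counts are proportional to the
    volume extents and sized to approximately ``n_target`` vertices.
    """
    if n_target < 8:
        raise ValueError("n_target must be >= 8")
    shape = np.asarray(volume_shape, dtype=float)
    ext = shape - 1.0
    scale = (n_target / np.prod(ext)) ** (1.0 / 3.0)
    counts = np.maximum(2, np.round(ext * scale).astype(int))
    axes = [np.linspace(0, ext[a], counts[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    verts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def vid(i, j, k):
        return (i * counts[1] + j) * counts[2] + k

    tets = []
    for i in range(counts[0] - 1):
        for j in range(counts[1] - 1):
            for k in range(counts[2] - 1):
                corner_ids = {}
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            corner_ids[(dx, dy, dz)] = vid(i + dx, j + dy, k + dz)
                for perm in _KUHN_PERMS:
                    path = [(0, 0, 0)]
                    cur = [0, 0, 0]
                    for axis in perm:
                        cur = cur.copy()
                        cur[axis] = 1
                        path.append(tuple(cur))
                    tets.append([corner_ids[p] for p in path])
    tets = _orient_tets(verts, np.asarray(tets, dtype=np.intp))
    is_corner = np.zeros(len(verts), dtype=bool)
    on_ext = [np.isin(verts[:, a], (0.0, ext[a])) for a in range(3)]
    is_corner[on_ext[0] & on_ext[1] & on_ext[2]] = True
    return TetMesh(verts, tets, is_corner)


def uniform_tet_mesh(n_target: int, volume_shape, mask: BinaryMask,
                     seed: int = 0, max_iter: int = 60) -> TetMesh:
    """Isotropic-tetrahedron baseline: particle optimization under rho = 1."""
    metric = MetricTensorField()  # uniform
    init = initialize_particles(n_target, metric, mask, seed=seed)
    opt = optimize_particles(init, metric, mask, max_iter=max_iter)
    return build_tet_mesh(opt, volume_shape)


def feature_mesh(n_particles: int, density: DensityField, mask: BinaryMask,
                 volume_shape, seed: int = 0, max_iter: int = 60) -> TetMesh:
    """End-to-end adaptive mesh: density-aware particles + Delaunay + corners."""
    metric = MetricTensorField.from_density(density)
    measure = embedding_measure(density, mask)
    sigma = kernel_width(measure, n_particles)
    init = initialize_particles(n_particles, metric, mask, seed=seed, sigma=sigma)
    opt = optimize_particles(init, metric, mask, max_iter=max_iter)
    return build_tet_mesh(opt, volume_shape)
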