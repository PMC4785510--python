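"""Boundary-based 3D-2D registration used to initialize the intensity DIR.

Instead of comparing full DRRs, this stage deforms only the body *surface*
voxels, projects them onto each detector by perspective splatting, and
matches the projected outline against the measured projection boundaries.
The energy is

    E_bound(D) = mu * L(D)
               + sum_m sum_points dist_min(projected point, target boundary)^2

with dist_min the nearest Euclidean distance (k-d tree) in detector pixels.
Because projected surface voxels from the far side of the body can land
inside the silhouette, each angle computes two projections: one without
kernels (raw point deposits) and one with Gaussian footprints; the
with-kernel image is thresholded into a filled silhouette whose rim band
filters the raw deposits down to true outline points.

The splat footprint follows perspective similar triangles: a voxel at
source distance d1 whose ray meets the detector at distance d2 has splat
radius r = voxel_scale * d2 / d1 and Gaussian width sigma = 0.57 * r; the
footprint covers a 3*sigma support and is normalized to unit deposited
mass.  The distance-term gradient is a central finite difference with step
delta_d per vertex component, restricted to vertices whose one-ring
touches a surface voxel (the term does not depend on the others).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .deform import locate_points
from .features import BinaryMask
from .meshing import TetMesh
from .project import ConeBeamGeometry, ProjectionImage
from .register import MeshGraph, laplacian_energy_grad

SPLAT_SIGMA_COEFF = 0.57
DEFAULT_DELTA_D = 0.5  # voxels, finite-difference step
DEFAULT_BAND_HALFWIDTH = 1.5  # pixels, silhouette rim band


def splat_sigma(r: float) -> float:
    """Gaussian footprint width for a splat of radius r: sigma = 0.57 r."""
    if r <= 0:
        raise ValueError("splat radius must be positive")
    return SPLAT_SIGMA_COEFF * r


def dynamic_splat_radius(voxel_scale, d1, d2):
    """Perspective splat radius from similar triangles: r = voxel_scale * d2/d1.

    d1 is the source-to-voxel distance, d2 the source-to-detector distance
    along the same ray (scalars or arrays); when d1 = d2 the splat radius
    equals the voxel scale.
    """
    if np.any(np.asarray(d1) <= 0) or np.any(np.asarray(d2) <= 0):
        raise ValueError("distances must be positive")
    return voxel_scale * np.asarray(d2) / np.asarray(d1)


@dataclass
class SplatKernelSpec:
    r: float

    @property
    def sigma(self) -> float:
        return splat_sigma(self.r)

    @property
    def support_radius(self) -> float:
        return 3.0 * self.sigma


@dataclass
class SurfaceVoxelSet:
    coords: np.ndarray  # (n, 3) voxel-center index coordinates
    values: np.ndarray  # per-voxel intensity (1 for masks)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class BoundaryPointSet2D:
    points: np.ndarray  # (n, 2) detector (row, col) coordinates

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) == 0:
            raise ValueError("empty boundary point set")
        self.tree = cKDTree(self.points)

    def __len__(self) -> int:
        return len(self.points)


def extract_surface_voxels(mask: BinaryMask) -> SurfaceVoxelSet:
    """Mask voxels with at least one background 6-neighbor."""
    m = mask.data
    if not np.any(m):
        raise ValueError("empty mask")
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = m & ~eroded
    coords = np.argwhere(surf).astype(float)
    return SurfaceVoxelSet(coords, np.ones(len(coords)))


def extract_projection_boundary(projection_mask: ProjectionImage | np.ndarray
                                ) -> BoundaryPointSet2D:
    """Boundary pixels of a binary 2D mask (mask minus its erosion)."""
    m = projection_mask.pixels if isinstance(projection_mask, ProjectionImage) \
        else np.asarray(projection_mask)
    m = m > 0.5
    if not np.any(m):
        raise ValueError("empty projection mask")
    eroded = ndimage.binary_erosion(m, border_value=0)
    return BoundaryPointSet2D(np.argwhere(m & ~eroded).astype(float))


def splat_project(voxels: SurfaceVoxelSet, geom: ConeBeamGeometry,
                  volume, with_kernel: bool = True,
                  world_coords: np.ndarray | None = None) -> ProjectionImage:
    """Project surface voxels onto the detector by splatting.

    ``volume`` supplies the index->world mapping and voxel scale (mean
    spacing).  ``world_coords`` overrides the voxel positions (already
    deformed, in world mm).  Without kernels each voxel deposits its value
    into the single nearest pixel; with kernels it deposits a normalized
    Gaussian footprint of dynamic radius r = voxel_scale * d2 / d1.
    Footprints entirely off the detector are skipped.
    """
    nr, nc = geom.det_shape
    img = np.zeros((nr, nc))
    if world_coords is None:
        world_coords = volume.index_to_world(voxels.coords)
    row, col, d1, d2 = geom.project_points(world_coords)
    voxel_scale = float(np.mean(volume.spacing))
    if not with_kernel:
        r_i = np.round(row).astype(int)
        c_i = np.round(col).astype(int)
        ok = (r_i >= 0) & (r_i < nr) & (c_i >= 0) & (c_i < nc)
        np.add.at(img, (r_i[ok], c_i[ok]), voxels.values[ok])
        return ProjectionImage(img, meaning="boundary")
    r_mm = dynamic_splat_radius(voxel_scale, d1, d2)
    sigma_px = SPLAT_SIGMA_COEFF * r_mm / geom.pixel_pitch_mm
    support = np.maximum(np.ceil(3.0 * sigma_px).astype(int), 1)
    # vectorize by grouping voxels with equal integer support radius
    for s in np.unique(support):
        grp = np.flatnonzero(support == s)
        rc, cc = row[grp], col[grp]
        off = np.arange(-s, s + 1)
        rr = np.floor(rc)[:, None] + off[None, :]  # (k, 2s+1)
        ccg = np.floor(cc)[:, None] + off[None, :]
        g = np.exp(
            -((rr[:, :, None] - rc[:, None, None]) ** 2
              + (ccg[:, None, :] - cc[:, None, None]) ** 2)
            / (2.0 * sigma_px[grp][:, None, None] ** 2)
        )
        tot = g.sum(axis=(1, 2))
        ok_vox = tot > 0
        g *= (voxels.values[grp] / np.where(ok_vox, tot, 1.0))[:, None, None]
        ri = np.broadcast_to(rr[:, :, None], g.shape).astype(int)
        ci = np.broadcast_to(ccg[:, None, :], g.shape).astype(int)
        inb = ok_vox[:, None, None] & (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
        np.add.at(img, (ri[inb], ci[inb]), g[inb])
    return ProjectionImage(img, meaning="boundary")


def filter_projected_boundary(no_kernel: ProjectionImage,
                              with_kernel: ProjectionImage,
                              band_halfwidth: float = DEFAULT_BAND_HALFWIDTH
                              ) -> BoundaryPointSet2D:
    """Keep only raw-deposit pixels on the silhouette rim.

    The with-kernel image is thresholded (Otsu) into a filled silhouette;
    pixels of the no-kernel image within ``band_halfwidth`` pixels of the
    silhouette boundary survive.  This removes surface-voxel projections
    landing inside the outline (far-side voxels).
    """
    from skimage.filters import threshold_otsu

    wk = with_kernel.pixels
    if wk.max() <= 0:
        raise ValueError("empty with-kernel silhouette image")
    thr = threshold_otsu(wk)
    sil = ndimage.binary_fill_holes(wk > thr)
    if not np.any(sil):
        raise ValueError("empty silhouette after thresholding")
    rim = sil & ~ndimage.binary_erosion(sil, border_value=0)
    dist_to_rim = ndimage.distance_transform_edt(~rim)
    hits = no_kernel.pixels > 0
    keep = hits & (dist_to_rim <= band_halfwidth)
    if not np.any(keep):
        raise ValueError("no projected boundary pixels survived filtering")
    return BoundaryPointSet2D(np.argwhere(keep).astype(float))


class _BoundaryModel:
    """Cached state for the boundary energy at fixed point selection.

    Selection (which surface voxels are outline points at each angle) is
    recomputed per full energy evaluation; within the finite-difference
    gradient it stays frozen and only retained point positions move.
    """

    def __init__(self, surface: SurfaceVoxelSet, targets, geoms, mesh: TetMesh,
                 volume, band_halfwidth: float = DEFAULT_BAND_HALFWIDTH):
        self.surface = surface
        self.targets = targets
        self.geoms = geoms
        self.mesh = mesh
        self.volume = volume
        self.band = band_halfwidth
        self.assign = locate_points(surface.coords, mesh)
        self.W = self.assign.weights_matrix  # (n_surf, n_verts)
        # vertices whose one-ring touches a surface voxel
        touched = np.unique(mesh.tets[self.assign.tet_ids].ravel())
        self.active_vertices = touched

    def deformed_world(self, displacements: np.ndarray) -> np.ndarray:
        """World positions of the deformed surface voxels.

        D is a pull field (the deformed image at x samples the source at
        x + D(x)), so a source surface point at s appears near s - D(s) in
        the deformed configuration; keeping that sign here makes the
        optimized D directly usable as the intensity-DIR warm start.
        """
        dv = self.W @ displacements  # voxel units
        return self.volume.index_to_world(self.surface.coords - dv)

    def select(self, displacements: np.ndarray) -> list[np.ndarray]:
        """Per angle: indices of surface voxels whose raw deposit is on the rim."""
        world = self.deformed_world(displacements)
        selections = []
        for geom in self.geoms:
            no_k = splat_project(self.surface, geom, self.volume,
                                 with_kernel=False, world_coords=world)
            with_k = splat_project(self.surface, geom, self.volume,
                                   with_kernel=True, world_coords=world)
            try:
                kept = filter_projected_boundary(no_k, with_k, self.band)
            except ValueError:
                selections.append(np.array([], dtype=np.intp))
                continue
            nr, nc = geom.det_shape
            keep_mask = np.zeros((nr, nc), dtype=bool)
            kp = kept.points.astype(int)
            keep_mask[kp[:, 0], kp[:, 1]] = True
            row, col, _, _ = geom.project_points(world)
            r_i = np.round(row).astype(int)
            c_i = np.round(col).astype(int)
            ok = (r_i >= 0) & (r_i < nr) & (c_i >= 0) & (c_i < nc)
            sel = np.flatnonzero(ok)
            sel = sel[keep_mask[r_i[sel], c_i[sel]]]
            selections.append(sel.astype(np.intp))
        return selections

    def distance_energy(self, displacements: np.ndarray,
                        selections: list[np.ndarray]) -> float:
        world = self.deformed_world(displacements)
        e = 0.0
        for geom, target, sel in zip(self.geoms, self.targets, selections):
            if len(sel) == 0:
                return 1e12  # degenerate configuration during line search
            row, col, _, _ = geom.project_points(world[sel])
            d, _ = target.tree.query(np.column_stack([row, col]))
            e += float(np.sum(d * d))
        return e

    def energy_grad(self, displacements: np.ndarray, delta_d: float,
                    selections: list[np.ndarray] | None = None):
        """Distance energy and central-finite-difference gradient.

        ``selections`` allows reuse of a previously computed point selection
        (the Fig-8-style filter output is piecewise constant in D, so it is
        refreshed once per optimizer iteration rather than per line-search
        probe).
        """
        if selections is None:
            selections = self.select(displacements)
        if all(len(s) == 0 for s in selections):
            raise ValueError("empty filtered boundary at every angle")
        dv = self.W @ displacements  # (n_surf, 3) voxel units
        e0 = 0.0
        grad_pts = np.zeros_like(dv)
        for geom, target, sel in zip(self.geoms, self.targets, selections):
            if len(sel) == 0:
                e0 += 1e12  # degenerate configuration during line search
                continue
            coords = self.surface.coords[sel]

            def point_dist2(dv_sel):
                world = self.volume.index_to_world(coords - dv_sel)
                row, col, _, _ = geom.project_points(world)
                d, _ = target.tree.query(np.column_stack([row, col]))
                return d * d

            e0 += float(np.sum(point_dist2(dv[sel])))
            # central difference per projected point and axis; the per-point
            # displacement is linear in D, so chaining through W^T reproduces
            # the per-vertex-component difference quotient to O(delta_d^2)
            for ax in range(3):
                step = np.zeros(3)
                step[ax] = delta_d
                ep = point_dist2(dv[sel] + step)
                em = point_dist2(dv[sel] - step)
                grad_pts[sel, ax] += (ep - em) / (2.0 * delta_d)
        grad = self.W.T @ grad_pts
        return e0, grad, selections


def boundary_energy_grad(displacements, mesh: TetMesh,
                         surface: SurfaceVoxelSet, targets, geoms, volume,
                         mu: float = 10.0, delta_d: float = DEFAULT_DELTA_D,
                         graph: MeshGraph | None = None,
                         model: _BoundaryModel | None = None):
    """Total boundary energy mu*L(D) + distance term, with gradient."""
    d = np.asarray(displacements, dtype=float).reshape(mesh.n_vertices, 3)
    if model is None:
        model = _BoundaryModel(surface, targets, geoms, mesh, volume)
    if graph is None:
        graph = MeshGraph.from_mesh(mesh)
    e_dist, g_dist, _ = model.energy_grad(d, delta_d)
    e_reg, g_reg = laplacian_energy_grad(d, graph)
    return mu * e_reg + e_dist, mu * g_reg + g_dist


def register_boundary(mask3d: BinaryMask, target_boundaries, geoms,
                      mesh: TetMesh, volume, mu: float = 10.0,
                      max_iter: int = 30, delta_d: float = DEFAULT_DELTA_D,
                      d_init: np.ndarray | None = None):
    """Optimize the primary DVF against 2D projection boundaries.

    Returns the vertex DVF intended as the warm start for the intensity
    registration.
    """
    surface = extract_surface_voxels(mask3d)
    model = _BoundaryModel(surface, target_boundaries, geoms, mesh, volume)
    graph = MeshGraph.from_mesh(mesh)
    n = mesh.n_vertices
    d0 = np.zeros((n, 3)) if d_init is None else \
        np.array(d_init, dtype=float).reshape(n, 3)
    cache = {"sel": model.select(d0)}

    def fun(x):
        d = x.reshape(n, 3)
        e_dist, g_dist, _ = model.energy_grad(d, delta_d, cache["sel"])
        e_reg, g_reg = laplacian_energy_grad(d, graph)
        return mu * e_reg + e_dist, (mu * g_reg + g_dist).ravel()

    def refresh(xk):
        cache["sel"] = model.select(xk.reshape(n, 3))

    res = minimize(fun, d0.ravel(), jac=True, method="L-BFGS-B",
                   callback=refresh,
                   options={"maxiter": max_iter, "gtol": 1e-6, "ftol": 1e-12})
    return res.x.reshape(n, 3)
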