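"""Cone-beam forward projection: Siddon line integrals and the noise model.

The source rotates about the volume's z axis at distance SAD (mm) from the
isocenter; a flat detector sits opposite at SDD - SAD, perpendicular to the
central ray.  Detector pixels are indexed row-major with (0, 0) at the
top-left as seen from the source: columns run along u = (-sin t, cos t, 0)
and rows run downward along -z.

Each pixel value is the exact line integral of the volume along the ray
from the source to the pixel center, computed by the parametric (Siddon)
traversal: all voxel-boundary crossing parameters are merged, and each
inter-crossing segment contributes (segment length in mm) x (intensity of
the voxel containing its midpoint).  The per-voxel lengths are optionally
returned as a sparse projection matrix P with entries w^(alpha, beta), so
a DRR is the matrix-vector product P @ U.ravel().

Measured projections follow the counting noise model
I_i = Poisson(I0 * exp(-p_i)) + Normal(0, sigma_e^2) with defaults
I0 = 1e5 photons and sigma_e^2 = 10; noisy intensities are converted back
to line integrals via -ln(max(I, 1) / I0) for use in the similarity term.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .volume import Volume

DEFAULT_I0 = 1.0e5
DEFAULT_SIGMA_E2 = 10.0


@dataclass
class ConeBeamGeometry:
    angle_deg: float
    sad_mm: float = 1000.0  # source to isocenter
    sdd_mm: float = 1500.0  # source to detector
    det_shape: tuple[int, int] = (96, 96)  # (rows, cols)
    pixel_pitch_mm: float = 1.6
    isocenter_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.sad_mm <= 0 or self.sdd_mm <= 0:
            raise ValueError("source distances must be positive")
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float).reshape(3)

    @property
    def _frame(self):
        t = np.deg2rad(self.angle_deg)
        toward = -np.array([np.cos(t), np.sin(t), 0.0])  # source -> isocenter
        u = np.array([-np.sin(t), np.cos(t), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return toward, u, v

    @property
    def source_pos(self) -> np.ndarray:
        toward, _, _ = self._frame
        return self.isocenter_mm - self.sad_mm * toward

    @property
    def detector_center(self) -> np.ndarray:
        toward, _, _ = self._frame
        return self.source_pos + self.sdd_mm * toward

    def pixel_centers(self) -> np.ndarray:
        """(rows, cols, 3) world positions of all detector pixel centers."""
        _, u, v = self._frame
        nr, nc = self.det_shape
        jj = (np.arange(nc) - (nc - 1) / 2.0) * self.pixel_pitch_mm
        ii = ((nr - 1) / 2.0 - np.arange(nr)) * self.pixel_pitch_mm
        return (self.detector_center
                + ii[:, None, None] * v
                + jj[None, :, None] * u)

    def project_points(self, world_pts: np.ndarray):
        """Perspective-project world points onto the detector.

        Returns (row, col) continuous pixel coordinates and the distances
        d1 (source to point) and d2 (source to detector intersection).
        """
        toward, u, v = self._frame
        src = self.source_pos
        rel = np.asarray(world_pts, dtype=float) - src
        depth = rel @ toward
        t = self.sdd_mm / depth
        foot = src + t[..., None] * rel
        fc = foot - self.detector_center
        col = (fc @ u) / self.pixel_pitch_mm + (self.det_shape[1] - 1) / 2.0
        row = (self.det_shape[0] - 1) / 2.0 - (fc @ v) / self.pixel_pitch_mm
        d1 = np.linalg.norm(rel, axis=-1)
        d2 = np.linalg.norm(foot - src, axis=-1)
        return row, col, d1, d2

    def check_coverage(self, vol: Volume) -> bool:
        """Warn when the detector misses part of the volume's footprint."""
        n = np.array(vol.shape, dtype=float) - 1.0
        corners_idx = np.array([[x, y, z] for x in (0, n[0]) for y in (0, n[1])
                                for z in (0, n[2])])
        row, col, _, _ = self.project_points(vol.index_to_world(corners_idx))
        nr, nc = self.det_shape
        ok = (row.min() >= -0.5 and row.max() <= nr - 0.5
              and col.min() >= -0.5 and col.max() <= nc - 0.5)
        if not ok:
            warnings.warn("detector does not cover the projected volume footprint")
        return ok


@dataclass
class ProjectionImage:
    pixels: np.ndarray
    meaning: str = "line_integral"  # line_integral | noisy_intensity | drr | boundary

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection contains non-finite pixels")


def default_geometries(n_angles: int, vol: Volume, det_shape=(96, 96),
                       pixel_pitch_mm: float = 1.6, sad_mm: float = 1000.0,
                       sdd_mm: float = 1500.0) -> list[ConeBeamGeometry]:
    """Equally spaced gantry angles over 360 degrees, centered on the volume."""
    iso = vol.center_world
    return [
        ConeBeamGeometry(angle_deg=a, sad_mm=sad_mm, sdd_mm=sdd_mm,
                         det_shape=det_shape, pixel_pitch_mm=pixel_pitch_mm,
                         isocenter_mm=iso)
        for a in np.linspace(0.0, 360.0, n_angles, endpoint=False)
    ]


def siddon_weights(vol: Volume, geom: ConeBeamGeometry) -> sparse.csr_matrix:
    """Sparse projection matrix of per-voxel intersection lengths (mm).

    Fully vectorized over rays: on a regular grid every ray crosses the same
    family of axis planes, so all crossing parameters form a dense
    (n_rays, nx+ny+nz+3) array that is clipped to each ray's [entry, exit]
    interval and sorted per row.
    """
    nx, ny, nz = vol.shape
    src = geom.source_pos
    pix = geom.pixel_centers().reshape(-1, 3)
    n_rays = len(pix)
    d = pix - src  # ray direction, parameter alpha in [0, 1]
    ray_len = np.linalg.norm(d, axis=1)

    # voxel boundary planes (world): origin - spacing/2 + i*spacing, i=0..n
    b0 = vol.origin - 0.5 * vol.spacing
    alphas = []
    amin = np.zeros(n_rays)
    amax = np.ones(n_rays)
    for ax, n_ax in enumerate((nx, ny, nz)):
        planes = b0[ax] + np.arange(n_ax + 1) * vol.spacing[ax]
        da = d[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (planes[None, :] - src[ax]) / da[:, None]
        par = np.abs(da) < 1e-12
        if np.any(par):
            inside = (src[ax] >= planes[0]) & (src[ax] <= planes[-1])
            # parallel rays: inside the slab -> no constraint; outside -> miss
            a[par] = np.nan
            a1 = np.where(par & inside, -np.inf, np.nan)
            a2 = np.where(par & inside, np.inf, np.nan)
            a1 = np.where(par & ~inside, np.inf, a1)
            a2 = np.where(par & ~inside, -np.inf, a2)
            lo = np.where(par, a1, np.minimum(a[:, 0], a[:, -1]))
            hi = np.where(par, a2, np.maximum(a[:, 0], a[:, -1]))
        else:
            lo = np.minimum(a[:, 0], a[:, -1])
            hi = np.maximum(a[:, 0], a[:, -1])
        amin = np.maximum(amin, lo)
        amax = np.minimum(amax, hi)
        alphas.append(a)
    amax = np.maximum(amax, amin)  # missing rays collapse to zero-length
    all_a = np.concatenate(alphas, axis=1)
    all_a = np.where(np.isnan(all_a), amin[:, None], all_a)
    all_a = np.clip(all_a, amin[:, None], amax[:, None])
    all_a = np.concatenate([amin[:, None], all_a, amax[:, None]], axis=1)
    all_a.sort(axis=1)

    seg = np.diff(all_a, axis=1)
    mid = 0.5 * (all_a[:, :-1] + all_a[:, 1:])
    lengths = seg * ray_len[:, None]
    pts = src + mid[..., None] * d[:, None, :]
    idx = np.floor((pts - b0) / vol.spacing).astype(np.int64)
    valid = (lengths > 1e-12) & np.all(
        (idx >= 0) & (idx < np.array([nx, ny, nz])), axis=-1
    )
    rows = np.broadcast_to(np.arange(n_rays)[:, None], lengths.shape)[valid]
    cols = (idx[..., 0] * ny + idx[..., 1]) * nz + idx[..., 2]
    cols = cols[valid]
    mat = sparse.csr_matrix(
        (lengths[valid], (rows, cols)), shape=(n_rays, nx * ny * nz)
    )
    mat.sum_duplicates()
    return mat


def siddon_project(vol: Volume, geom: ConeBeamGeometry,
                   want_weights: bool = False):
    """Ray-traced line-integral projection of a volume.

    Returns a :class:`ProjectionImage`; with ``want_weights`` also the sparse
    projection matrix so subsequent projections of warped volumes are plain
    matrix-vector products.
    """
    w = siddon_weights(vol, geom)
    p = (w @ vol.data.ravel()).reshape(geom.det_shape)
    img = ProjectionImage(p, meaning="line_integral")
    if want_weights:
        return img, w
    return img


def drr_from_dvf(u_original: Volume, mesh, displacements, geom: ConeBeamGeometry,
                 weights: sparse.csr_matrix | None = None,
                 assignment=None) -> ProjectionImage:
    """DRR of the deformed volume: P(theta) @ U_new(D)."""
    from .deform import grid_assignment, interpolate_dvf, warp_image

    if assignment is None:
        assignment = grid_assignment(mesh, u_original.shape)
    dv = interpolate_dvf(mesh, displacements, u_original.shape, assignment)
    u_new = warp_image(u_original, dv)
    if weights is None:
        weights = siddon_weights(u_original, geom)
    p = (weights @ u_new.data.ravel()).reshape(geom.det_shape)
    return ProjectionImage(p, meaning="drr")


def add_projection_noise(p: ProjectionImage, i0: float = DEFAULT_I0,
                         sigma_e2: float = DEFAULT_SIGMA_E2,
                         seed: int = 0) -> tuple[ProjectionImage, ProjectionImage]:
    """Apply the counting noise model to a line-integral projection.

    Returns ``(intensity_image, noisy_line_integral_image)``; the latter is
    -ln(max(I, 1)/I0), the form consumed by the registration similarity term.
    """
    if i0 <= 0:
        raise ValueError("incident intensity I0 must be positive")
    if np.any(p.pixels < 0):
        raise ValueError("line integrals must be non-negative")
    rng = np.random.default_rng(seed)
    lam = i0 * np.exp(-p.pixels)
    intensity = rng.poisson(lam).astype(float)
    if sigma_e2 > 0:
        intensity += rng.normal(0.0, np.sqrt(sigma_e2), size=p.pixels.shape)
    intensity = np.maximum(intensity, 0.0)
    line_int = -np.log(np.maximum(intensity, 1.0) / i0)
    return (ProjectionImage(intensity, meaning="noisy_intensity"),
            ProjectionImage(line_int, meaning="line_integral"))
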