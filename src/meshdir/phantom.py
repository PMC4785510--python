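"""Synthetic nested-ellipsoid phantoms and analytic ground-truth deformations.

Every downstream stage of the pipeline (feature extraction, meshing,
projection, registration, evaluation) is exercised on volumes produced here,
so the generator is deliberately simple and fully deterministic: piecewise
constant ellipsoids with attenuation-like intensities, plus smooth analytic
displacement fields (translation / affine / sinusoidal) whose values are
known in closed form at any point.

The displacement convention is *pull* (backward mapping): the vector stored
at output voxel (a, b, c) points to the location in the source image whose
intensity the output voxel takes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume


@dataclass
class Ellipsoid:
    center: np.ndarray  # voxel index coordinates
    semiaxes: np.ndarray  # voxel units
    intensity: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semiaxes = np.asarray(self.semiaxes, dtype=float).reshape(3)
        if np.any(self.semiaxes <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        q = (np.asarray(pts, dtype=float) - self.center) / self.semiaxes
        return np.einsum("...i,...i->...", q, q) <= 1.0


def make_phantom(shape, ellipsoids, spacing=(1.0, 1.0, 1.0),
                 allow_clip: bool = False) -> Volume:
    """Paint nested ellipsoids (listed outer to inner) onto a zero background.

    Each descriptor overwrites the previous ones inside its support, so the
    innermost containing ellipsoid wins.  An empty list yields an all-zero
    volume.  An ellipsoid reaching outside the raster is rejected unless
    ``allow_clip`` is set (degenerate full-cover cases).
    """
    shape = tuple(int(s) for s in shape)
    data = np.zeros(shape)
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).astype(float)
    for e in ellipsoids:
        if isinstance(e, dict):
            e = Ellipsoid(**e)
        if not allow_clip and (
            np.any(e.center - e.semiaxes < -0.5)
            or np.any(e.center + e.semiaxes > np.array(shape) - 0.5)
        ):
            raise ValueError(
                f"ellipsoid at {e.center} with semi-axes {e.semiaxes} "
                f"exceeds the raster bounds {shape}"
            )
        data[e.contains(pts)] = e.intensity
    return Volume(data, spacing=spacing)


def default_phantom(n: int = 64, body_intensity: float = 0.02,
                    inner_intensity: float = 0.04) -> Volume:
    """Two-ellipsoid phantom: a water-like body and a denser inner structure.

    Intensities are linear attenuation coefficients in mm^-1 (0.02 is close
    to water at CT energies), so ray line integrals through the body are of
    order one — the same scale the projection noise model expects.
    """
    c = (n - 1) / 2.0
    return make_phantom(
        (n, n, n),
        [
            Ellipsoid(center=(c, c, c), semiaxes=(0.42 * n, 0.34 * n, 0.40 * n),
                      intensity=body_intensity),
            Ellipsoid(center=(c + 0.08 * n, c - 0.04 * n, c),
                      semiaxes=(0.16 * n, 0.12 * n, 0.18 * n),
                      intensity=inner_intensity),
        ],
    )


@dataclass
class AnalyticDVF:
    """Closed-form displacement field in voxel units (pull convention).

    kind:
      * ``translation`` — constant vector ``amplitude``;
      * ``sinusoidal``  — per axis, amplitude_d * sin(2*pi*x_d / wavelength_d);
      * ``affine``      — A @ x + b with ``matrix`` A and ``amplitude`` b.
    """

    kind: str
    amplitude: np.ndarray = field(default_factory=lambda: np.zeros(3))
    wavelength: np.ndarray = field(default_factory=lambda: np.full(3, 64.0))
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("translation", "sinusoidal", "affine"):
            raise ValueError(f"unknown analytic DVF kind: {self.kind!r}")
        self.amplitude = np.asarray(self.amplitude, dtype=float).reshape(3)
        self.wavelength = np.asarray(self.wavelength, dtype=float).reshape(3)
        if np.any(self.wavelength <= 0):
            raise ValueError("wavelengths must be positive")
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return evaluate_dvf(self, points)


def evaluate_dvf(dvf: AnalyticDVF, points: np.ndarray) -> np.ndarray:
    """Evaluate the analytic field at (..., 3) index-coordinate points."""
    pts = np.asarray(points, dtype=float)
    if dvf.kind == "translation":
        return np.broadcast_to(dvf.amplitude, pts.shape).copy()
    if dvf.kind == "sinusoidal":
        return dvf.amplitude * np.sin(2.0 * np.pi * pts / dvf.wavelength)
    # affine
    mat = dvf.matrix if dvf.matrix is not None else np.zeros((3, 3))
    return pts @ mat.T + dvf.amplitude


def warp_groundtruth(vol: Volume, dvf: AnalyticDVF) -> Volume:
    """Warp a volume with an analytic field: out(a) = in(a + dvf(a)).

    Trilinear (order-1) resampling; out-of-range samples take background 0.
    """
    nx, ny, nz = vol.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).astype(float)
    pulled = pts + evaluate_dvf(dvf, pts)
    out = map_coordinates(
        vol.data, [pulled[..., 0], pulled[..., 1], pulled[..., 2]],
        order=1, mode="constant", cval=0.0,
    )
    return Volume(out, spacing=vol.spacing, origin=vol.origin)
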