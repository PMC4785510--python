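"""Trilinear sampling with exact partial derivatives.

The registration energy differentiates the warped image with respect to the
vertex displacements, which requires the derivative of the trilinear
interpolant itself (piecewise bilinear in the other two axes).  Samples
outside the raster evaluate to the background value 0 with zero gradient,
implemented by interpolating into a one-voxel zero pad.
"""
from __future__ import annotations

import numpy as np


def _gather(padded: np.ndarray, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
    return padded[i, j, k]


def _prep(data: np.ndarray, pts: np.ndarray):
    pts = np.asarray(pts, dtype=np.float64)
    padded = np.pad(data, 1, mode="constant")
    p = pts + 1.0  # shift into padded frame
    # clamp so far-outside points land in the zero pad (value and grad 0)
    p = np.clip(p, 0.0, np.array(data.shape) + 1.0 - 1e-9)
    i0 = np.floor(p).astype(np.intp)
    np.minimum(i0, np.array(data.shape), out=i0)
    f = p - i0
    c = np.empty(pts.shape[:-1] + (2, 2, 2))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                c[..., di, dj, dk] = _gather(
                    padded, i0[..., 0] + di, i0[..., 1] + dj, i0[..., 2] + dk
                )
    return c, f


def trilinear(data: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Sample ``data`` at continuous index coordinates ``pts`` (..., 3)."""
    c, f = _prep(data, pts)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    cx = c[..., 0, :, :] * (1 - fx)[..., None, None] + c[..., 1, :, :] * fx[..., None, None]
    cxy = cx[..., 0, :] * (1 - fy)[..., None] + cx[..., 1, :] * fy[..., None]
    return cxy[..., 0] * (1 - fz) + cxy[..., 1] * fz


def trilinear_grad(data: np.ndarray, pts: np.ndarray):
    """Sample values and the exact spatial gradient of the interpolant.

    Returns ``(values, grads)`` with ``grads`` of shape (..., 3), in units of
    intensity per voxel along each index axis.
    """
    c, f = _prep(data, pts)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    wx = np.stack([1 - fx, fx], axis=-1)
    wy = np.stack([1 - fy, fy], axis=-1)
    wz = np.stack([1 - fz, fz], axis=-1)

    cx = np.einsum("...ijk,...i->...jk", c, wx)
    cxy = np.einsum("...jk,...j->...k", cx, wy)
    val = np.einsum("...k,...k->...", cxy, wz)

    dx = c[..., 1, :, :] - c[..., 0, :, :]
    gx = np.einsum("...k,...k->...", np.einsum("...jk,...j->...k", dx, wy), wz)
    cy = np.einsum("...ijk,...i->...jk", c, wx)
    dy = cy[..., 1, :] - cy[..., 0, :]
    gy = np.einsum("...k,...k->...", dy, wz)
    gz = cxy[..., 1] - cxy[..., 0]
    return val, np.stack([gx, gy, gz], axis=-1)
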