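"""3D scalar raster container and I/O.

Conventions used throughout the package:

* arrays are indexed ``data[a, b, c]`` with axes (x, y, z);
* voxel centers sit at integer indices (0-based);
* ``world = origin + index * spacing`` (mm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


@dataclass
class Volume:
    """A 3D scalar image with physical spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in attenuation-like units (mm^-1 for CT stand-ins).
    spacing : 3-vector, mm/voxel.
    origin : 3-vector, mm (world position of voxel (0, 0, 0)).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("all volume dimensions must be >= 2")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) index coordinates to world mm."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    @property
    def center_world(self) -> np.ndarray:
        """World position of the raster center (used as isocenter)."""
        return self.index_to_world((np.array(self.shape) - 1) / 2.0)

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array of index coordinates."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)

    def downsample(self, factor: int) -> "Volume":
        """Block-mean downsampling by an integer factor (for multiresolution).

        The coarse voxel center averages a ``factor^3`` block, so the coarse
        origin shifts by ``(factor-1)/2`` fine voxels per axis.
        """
        if factor == 1:
            return self
        from skimage.measure import block_reduce

        if any(s // factor < 8 for s in self.shape):
            raise ValueError("downsampling would produce a dimension < 8")
        n = [s - s % factor for s in self.shape]
        cropped = self.data[: n[0], : n[1], : n[2]]
        coarse = block_reduce(cropped, (factor,) * 3, np.mean)
        return Volume(
            coarse,
            spacing=self.spacing * factor,
            origin=self.origin + (factor - 1) / 2.0 * self.spacing,
        )


def read_volume(path: str) -> Volume:
    """Read a MetaImage/NRRD volume (axis order converted to (x, y, z))."""
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T  # sitk returns (z, y, x)
    return Volume(data, spacing=np.array(img.GetSpacing()), origin=np.array(img.GetOrigin()))


def write_volume(vol: Volume, path: str) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


def write_dvf(dvf_components: np.ndarray, spacing, origin, path: str) -> None:
    """Write a 3-component displacement raster (shape (3, nx, ny, nz))."""
    comps = np.asarray(dvf_components)
    arr = np.ascontiguousarray(np.moveaxis(comps, 0, -1).transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(np.asarray(spacing, dtype=float)))
    img.SetOrigin(tuple(np.asarray(origin, dtype=float)))
    sitk.WriteImage(img, str(path))


def read_dvf(path: str) -> np.ndarray:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    return np.moveaxis(arr.transpose(2, 1, 0, 3), -1, 0)
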