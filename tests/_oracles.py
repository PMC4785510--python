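"""Independent numerical oracles shared across test modules."""
import numpy as np


def dense_ray_integral(vol, src, pix, n_steps=10000):
    """Line integral by uniform dense sampling inside the volume slab.

    Deliberately independent of the Siddon traversal: clips the ray to the
    volume's bounding slab analytically, then accumulates nearest-voxel
    intensities at midpoint samples.
    """
    d = pix - src
    b0 = vol.origin - 0.5 * vol.spacing
    b1 = b0 + np.array(vol.shape) * vol.spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = (b0 - src) / d
        a1 = (b1 - src) / d
    lo = max(np.nanmax(np.minimum(a0, a1)), 0.0)
    hi = min(np.nanmin(np.maximum(a0, a1)), 1.0)
    if hi <= lo:
        return 0.0
    ts = lo + (np.arange(n_steps) + 0.5) / n_steps * (hi - lo)
    pts = src + ts[:, None] * d
    idx = np.floor((pts - b0) / vol.spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    vals = np.zeros(n_steps)
    vals[ok] = vol.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return vals.sum() * np.linalg.norm(d) * (hi - lo) / n_steps
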