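"""Similarity and error metrics for images and displacement fields.

NCC is the conventional mean-subtracted normalized cross correlation
(range [-1, 1], 1 for identical inputs); NRMSE is the root-mean-square
error normalized by the target's root sum of squares (0 for identical
inputs).  Displacement fields are compared by concatenating the three
components inside the evaluation mask into a single vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricReport:
    ncc_image: float | None = None
    nrmse_image: float | None = None
    ncc_dvf: float | None = None
    nrmse_dvf: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def ncc(f_intp: np.ndarray, f: np.ndarray) -> float:
    a = np.asarray(f_intp, dtype=float).ravel()
    b = np.asarray(f, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        raise ValueError("NCC undefined for constant input (zero variance)")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def nrmse(f_intp: np.ndarray, f: np.ndarray) -> float:
    a = np.asarray(f_intp, dtype=float).ravel()
    b = np.asarray(f, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    denom = np.sum(b * b)
    if denom == 0:
        raise ValueError("NRMSE undefined for an all-zero target")
    return float(np.sqrt(np.sum((a - b) ** 2) / denom))


def image_metrics(est: np.ndarray, target: np.ndarray,
                  mask: np.ndarray | None = None) -> MetricReport:
    if mask is not None:
        est, target = est[mask], target[mask]
    return MetricReport(ncc_image=ncc(est, target), nrmse_image=nrmse(est, target))


def dvf_metrics(dv_est, dv_true, mask) -> MetricReport:
    """Compare two voxel displacement fields inside a mask.

    ``dv_est``/``dv_true``: sequences of three 3D component arrays.
    """
    m = np.asarray(mask, dtype=bool)
    if not np.any(m):
        raise ValueError("empty evaluation mask")
    est = np.concatenate([np.asarray(c)[m].ravel() for c in dv_est])
    true = np.concatenate([np.asarray(c)[m].ravel() for c in dv_true])
    try:
        ncc_val = ncc(est, true)
    except ValueError:  # constant field (e.g. the all-zero baseline)
        ncc_val = None
    return MetricReport(ncc_dvf=ncc_val, nrmse_dvf=nrmse(est, true))
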