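"""Rigid-body superposition helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import StructureError


def kabsch(
    target: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (R, t, rmsd) with R a proper rotation (det +1) such that
    ``R @ mobile[i] + t`` best matches ``target[i]``.
    """
    target = np.asarray(target, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if target.shape != mobile.shape or target.ndim != 2 or target.shape[1] != 3:
        raise StructureError("superposition needs two equal (n, 3) arrays")
    n = target.shape[0]
    if n < 3:
        raise StructureError(f"at least 3 matched atoms required, got {n}")
    cen_t = target.mean(axis=0)
    cen_m = mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - cen_t, mobile - cen_m)
    R = rot.as_matrix()
    t = cen_t - R @ cen_m
    residuals = mobile @ R.T + t - target
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return R, t, rmsd


def rotate_about_axis(
    coords: np.ndarray, point: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate coordinates about the line through `point` along `axis`."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    return rot.apply(coords - point) + point
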