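"""Chromatic aberration correction by a 2D affine transform.

The wavelength-dependent residual shift between color channels of a
microscope is static for a given optical path, so it can be calibrated
once from paired control points (e.g. DNA-PAINT nanoruler sites imaged in
both channels) and then applied to every dataset from the same setup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import AffineTransform2D, LocalizationTable

__all__ = ["AffineFitResult", "estimate_affine", "apply_affine", "pair_points"]


@dataclass
class AffineFitResult:
    """Estimated transform plus per-pair residual distances (px) and their RMS."""

    transform: AffineTransform2D
    residuals: np.ndarray
    rms_residual: float


def estimate_affine(pairs, translation_only: bool = False) -> AffineFitResult:
    """Least-squares affine transform mapping moving points onto reference points.

    Parameters
    ----------
    pairs
        Sequence of ``((x_ref, y_ref), (x_mov, y_mov))`` control-point pairs,
        or an ``(n, 4)`` array with columns ``x_ref, y_ref, x_mov, y_mov``.
    translation_only
        Fit only a translation (for e.g. dual-view camera registration).

    Raises on fewer than 3 pairs or on a collinear/degenerate design
    (condition number > 1e8).
    """
    arr = np.asarray([(*r, *m) for r, m in pairs] if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("pairs must be ((x_ref, y_ref), (x_mov, y_mov)) tuples or an (n, 4) array")
    n = len(arr)
    if n < 3:
        raise ValueError(f"need at least 3 control-point pairs; got {n}")
    ref = arr[:, 0:2]
    mov = arr[:, 2:4]

    if translation_only:
        t = ref.mean(axis=0) - mov.mean(axis=0)
        transform = AffineTransform2D(1.0, 0.0, 0.0, 1.0, t[0], t[1])
    else:
        design = np.column_stack([mov, np.ones(n)])
        if np.linalg.cond(design) > 1e8:
            raise ValueError("degenerate control-point design (collinear points?)")
        coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
        transform = AffineTransform2D(
            a=coef[0, 0], b=coef[1, 0], tx=coef[2, 0],
            c=coef[0, 1], d=coef[1, 1], ty=coef[2, 1],
        )
    residuals = np.linalg.norm(transform.apply(mov) - ref, axis=1)
    return AffineFitResult(transform, residuals, float(np.sqrt(np.mean(residuals**2))))


def apply_affine(table: LocalizationTable, transform: AffineTransform2D) -> LocalizationTable:
    """Map every localization position through the transform."""
    out = table.copy()
    xy = transform.apply(out.xy())
    out.df["x"] = xy[:, 0]
    out.df["y"] = xy[:, 1]
    return out


def pair_points(
    reference: np.ndarray, moving: np.ndarray, radius: float
) -> np.ndarray:
    """Automatic control-point pairing by mutual nearest neighbours.

    Returns an (n, 4) array ``x_ref, y_ref, x_mov, y_mov`` of pairs that are
    each other's nearest neighbour and closer than ``radius``.
    """
    reference = np.atleast_2d(reference)
    moving = np.atleast_2d(moving)
    if len(reference) == 0 or len(moving) == 0:
        return np.empty((0, 4))
    tree_ref = cKDTree(reference)
    tree_mov = cKDTree(moving)
    d_rm, idx_rm = tree_mov.query(reference)          # for each ref: nearest mov
    _d_mr, idx_mr = tree_ref.query(moving)            # for each mov: nearest ref
    out = []
    for i, (d, j) in enumerate(zip(d_rm, idx_rm)):
        if d <= radius and idx_mr[j] == i:
            out.append([*reference[i], *moving[j]])
    return np.asarray(out) if out else np.empty((0, 4))
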