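"""Core array types and soft-confusion aggregation for segmentation losses.

Arrays follow a single convention throughout the package: the class axis is
last, and the spatial part has rank 2 (H, W) or rank 3 (D, H, W).  A
probability map therefore has shape ``(*spatial, C)`` with ``C >= 2`` classes
and rows that sum to one; a label mask has shape ``(*spatial,)`` with integer
class ids in ``[0, C-1]``.  Losses only ever flatten over pixels, so 2D and 3D
inputs share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: tolerance on per-pixel probability sums
PROB_SUM_TOL = 1e-6


class ShapeError(ValueError):
    """Spatial/class shapes of two arrays disagree."""


class InvalidLabelError(ValueError):
    """A label mask contains a class id outside [0, n_classes-1]."""


class ParameterError(ValueError):
    """A loss/metric hyperparameter is outside its valid range."""


class ValidationError(ValueError):
    """An array violates a probability-map or mask invariant."""


def as_label_mask(mask) -> np.ndarray:
    """Coerce to an integer label mask of spatial rank 2 or 3."""
    arr = np.asarray(mask)
    if arr.ndim not in (2, 3):
        raise ShapeError(f"label mask must have spatial rank 2 or 3, got rank {arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValidationError("label mask has non-integral values")
        arr = rounded.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise InvalidLabelError(f"negative label {int(arr.min())} in mask")
    return arr


def validate_probability_map(p, renormalise: bool = False) -> np.ndarray:
    """Validate ``p`` as a probability map (class axis last, rows sum to 1).

    Parameters
    ----------
    p : array-like, shape (*spatial, C)
        Per-pixel class probabilities with spatial rank 2 or 3 and C >= 2.
    renormalise : bool
        If True, rows whose sums deviate from 1 beyond ``PROB_SUM_TOL`` are
        divided by their sum instead of raising.  Never applied silently.
    """
    arr = np.asarray(p, dtype=np.float64)
    if arr.ndim not in (3, 4):
        raise ShapeError(
            f"probability map must have rank 3 (H,W,C) or 4 (D,H,W,C), got rank {arr.ndim}"
        )
    if arr.shape[-1] < 2:
        raise ShapeError(f"probability map needs >= 2 classes, got C={arr.shape[-1]}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("probability map contains non-finite values")
    if arr.min() < 0 or arr.max() > 1 + PROB_SUM_TOL:
        raise ValidationError("probability map entries must lie in [0, 1]")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=PROB_SUM_TOL, rtol=0):
        if not renormalise:
            worst = float(np.abs(sums - 1.0).max())
            raise ValidationError(
                f"per-pixel class sums deviate from 1 by up to {worst:.3g} "
                f"(tolerance {PROB_SUM_TOL:g}); pass renormalise=True to rescale"
            )
        arr = arr / sums[..., None]
    return arr


def one_hot_encode(mask, n_classes: int) -> np.ndarray:
    """One-hot encode an integer label mask.

    Returns a ``(*spatial, n_classes)`` float array with exactly one 1 per
    pixel; per-pixel argmax of the result recovers the input mask exactly.
    """
    arr = as_label_mask(mask)
    if n_classes < 2:
        raise ParameterError(f"n_classes must be >= 2, got {n_classes}")
    if arr.size and arr.max() >= n_classes:
        raise InvalidLabelError(
            f"label {int(arr.max())} out of range for n_classes={n_classes}"
        )
    out = np.zeros(arr.shape + (n_classes,), dtype=np.float64)
    np.put_along_axis(out, arr[..., None], 1.0, axis=-1)
    return out


def argmax_decode(p) -> np.ndarray:
    """Per-pixel argmax over the class axis; ties go to the lowest class id."""
    return np.argmax(np.asarray(p), axis=-1)


def check_same_grid(p: np.ndarray, y: np.ndarray) -> None:
    if p.shape != y.shape:
        raise ShapeError(f"probability map shape {p.shape} != one-hot mask shape {y.shape}")


@dataclass(frozen=True)
class ConfusionTerms:
    """Per-class soft and hard confusion aggregates.

    ``tp_soft[c] = sum_i p0*y0``; ``fp_soft[c] = sum_i (p0*y1)**gamma``;
    ``fn_soft[c] = sum_i (p1*y0)**gamma`` where ``p0`` is the probability of
    class c, ``p1 = 1 - p0``, ``y0`` the one-hot indicator of class c and
    ``y1 = 1 - y0``.  At ``gamma=1`` the soft terms are plain sums.  Hard
    counts come from the per-pixel argmax of ``p``.
    """

    tp_soft: np.ndarray
    fp_soft: np.ndarray
    fn_soft: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    gamma: float
    n_pixels: int
    n_classes: int


def confusion_terms(p, y, gamma: float = 1.0) -> ConfusionTerms:
    """Aggregate per-class soft TP/FP/FN (gamma-exponentiated) and hard counts.

    ``gamma`` exponentiates each per-pixel error product before summation, the
    mechanism by which confident errors (products near 1) come to dominate the
    penalty.  ``0**gamma`` is taken as 0 for all gamma > 0.
    """
    if gamma <= 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    check_same_grid(p, y)
    C = p.shape[-1]
    pf = p.reshape(-1, C)
    yf = y.reshape(-1, C)
    tp_soft = (pf * yf).sum(axis=0)
    fp_base = pf * (1.0 - yf)
    fn_base = (1.0 - pf) * yf
    if gamma == 1.0:
        fp_soft = fp_base.sum(axis=0)
        fn_soft = fn_base.sum(axis=0)
    else:
        fp_soft = (fp_base**gamma).sum(axis=0)
        fn_soft = (fn_base**gamma).sum(axis=0)

    pred = np.argmax(pf, axis=1)
    true = np.argmax(yf, axis=1)
    tp = np.zeros(C, dtype=np.int64)
    fp = np.zeros(C, dtype=np.int64)
    fn = np.zeros(C, dtype=np.int64)
    for c in range(C):
        pc = pred == c
        tc = true == c
        tp[c] = int(np.count_nonzero(pc & tc))
        fp[c] = int(np.count_nonzero(pc & ~tc))
        fn[c] = int(np.count_nonzero(~pc & tc))
    return ConfusionTerms(
        tp_soft=tp_soft,
        fp_soft=fp_soft,
        fn_soft=fn_soft,
        tp=tp,
        fp=fp,
        fn=fn,
        gamma=float(gamma),
        n_pixels=pf.shape[0],
        n_classes=C,
    )
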