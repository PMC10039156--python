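"""Softmax-threshold post-processing: trade recall against precision after
training by replacing argmax with a tunable cutoff on the target-class
probability.

A pixel is labelled foreground iff its target-class softmax output ``s``
satisfies ``s >= T``.  For a binary map, ``T = 0.5`` reproduces per-pixel
argmax (ties at exactly 0.5 go to the foreground, matching the lowest-index
argmax convention only where no tie occurs).  Raising ``T`` shrinks the
predicted-positive set, so precision is favoured; lowering ``T`` favours
recall.  The sweep is only informative when the probabilities are calibrated:
an overconfident model's outputs sit at the extremes and barely respond to T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ParameterError, as_label_mask, validate_probability_map
from .metrics import bootstrap_ci, hard_overlap_metrics


def default_thresholds(start: float = 0.05, stop: float = 0.95,
                       step: float = 0.05) -> np.ndarray:
    """The standard sweep grid T in [0.05, 0.95] with step 0.05 (19 points)."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


def apply_threshold(p, target_class: int = 1, T: float = 0.5) -> np.ndarray:
    """Label a pixel ``target_class`` iff its class probability >= T.

    One-vs-rest for the named class; all other pixels are labelled 0.
    """
    if not (0 < T < 1):
        raise ParameterError(f"threshold T must lie in (0, 1), got {T}")
    p = validate_probability_map(p)
    C = p.shape[-1]
    if not (0 <= target_class < C):
        raise ParameterError(f"target_class {target_class} outside [0, {C - 1}]")
    s = p[..., target_class]
    return np.where(s >= T, target_class, 0).astype(np.int64)


@dataclass
class ThresholdSweep:
    """Recall/precision/Dice as a function of the softmax threshold."""

    rows: pd.DataFrame
    target_class: int
    n_images: int

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6g")


def threshold_sweep(preds, truths, thresholds=None, target_class: int = 1,
                    n_boot: int = 1000, seed: int = 0) -> ThresholdSweep:
    """Sweep T over a grid; per T, aggregate target-class recall/precision/Dice
    over images with 95% bootstrap confidence intervals.

    Truth masks are binarised one-vs-rest against ``target_class`` so the
    metrics refer to the target class alone.
    """
    thresholds = default_thresholds() if thresholds is None else np.asarray(
        thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ParameterError("threshold list is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ParameterError("thresholds must be strictly increasing")
    if len(preds) != len(truths):
        raise ParameterError(f"{len(preds)} predictions vs {len(truths)} truths")
    truths = [as_label_mask(t) for t in truths]
    binarised = [np.where(t == target_class, 1, 0) for t in truths]
    rows = []
    for T in thresholds:
        per_img = {"recall": [], "precision": [], "dice": []}
        for p, tb in zip(preds, binarised):
            mask = apply_threshold(p, target_class, float(T))
            mb = np.where(mask == target_class, 1, 0)
            ov = hard_overlap_metrics(mb, tb, 2)
            for m in per_img:
                per_img[m].append(ov[m][1])
        row = {"T": float(T)}
        for m, vals in per_img.items():
            row[m] = float(np.mean(vals))
            lo, hi = bootstrap_ci(vals, n_boot, seed)
            row[f"{m}_lo"] = lo
            row[f"{m}_hi"] = hi
        rows.append(row)
    return ThresholdSweep(rows=pd.DataFrame(rows), target_class=target_class,
                          n_images=len(preds))
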