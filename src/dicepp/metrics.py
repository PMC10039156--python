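"""Calibration (NLL, Brier) and overlap (Dice, Jaccard, recall, precision)
metrics with bootstrap standard errors.

NLL and Brier are strictly proper scoring rules: both are minimised in
expectation only by the true class distribution, so they reward calibrated
probabilities.  The overlap metrics are computed from hard per-class confusion
counts of argmax (or thresholded) masks and are insensitive to how confident
the probabilities are — which is exactly why a model can score well on Dice
while being badly miscalibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ParameterError,
    ShapeError,
    argmax_decode,
    as_label_mask,
    one_hot_encode,
)
from .losses import ce_loss


def nll(p, y) -> float:
    """Negative log likelihood of the truth under ``p``; identical to the CE
    loss (shared implementation)."""
    return float(ce_loss(p, y))


def brier(p, y) -> float:
    """Brier score: mean squared error between probabilities and one-hot
    truth, averaged over all N*C entries.  In [0, 1]; lower is better."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {y.shape}")
    return float(np.mean((y - p) ** 2))


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with the empty-class convention: 0/0 -> 1."""
    out = np.ones_like(num, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def hard_overlap_metrics(pred_mask, truth, n_classes: int) -> dict:
    """Per-class and mean Dice/Jaccard/recall/precision from hard counts.

    A class absent from both prediction and truth (TP=FP=FN=0) scores 1 on
    every metric, so a correctly-empty prediction is not penalised.  Returns
    per-class arrays plus ``mean`` (all classes) and ``foreground_mean``
    (classes >= 1) for each metric.
    """
    pred = as_label_mask(pred_mask)
    true = as_label_mask(truth)
    if pred.shape != true.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    tp = np.zeros(n_classes, dtype=np.float64)
    fp = np.zeros(n_classes, dtype=np.float64)
    fn = np.zeros(n_classes, dtype=np.float64)
    for c in range(n_classes):
        pc = pred == c
        tc = true == c
        tp[c] = np.count_nonzero(pc & tc)
        fp[c] = np.count_nonzero(pc & ~tc)
        fn[c] = np.count_nonzero(~pc & tc)
    out = {
        "dice": _safe_ratio(2 * tp, 2 * tp + fp + fn),
        "jaccard": _safe_ratio(tp, tp + fp + fn),
        "recall": _safe_ratio(tp, tp + fn),
        "precision": _safe_ratio(tp, tp + fp),
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
    for m in ("dice", "jaccard", "recall", "precision"):
        out[f"{m}_mean"] = float(out[m].mean())
        out[f"{m}_foreground_mean"] = float(out[m][1:].mean())
    return out


def bootstrap_se(values, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of the mean of per-image values.

    Resamples ``len(values)`` items with replacement ``n_boot`` times and
    returns the standard deviation of the resample means.  Deterministic
    given ``seed``.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ParameterError("bootstrap_se needs at least 2 values")
    if n_boot < 100:
        raise ParameterError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    return float(vals[idx].mean(axis=1).std())


def bootstrap_ci(values, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        return float(vals.mean()), float(vals.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


METRIC_COLUMNS = ("nll", "brier", "dice", "jaccard", "recall", "precision")


@dataclass
class MetricReport:
    """Per-image metric rows plus aggregate means and bootstrap SEs."""

    per_image: pd.DataFrame
    aggregate: dict
    se: dict
    n_boot: int
    seed: int
    per_class: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False, float_format="%.6g")

    def to_json(self, path=None):
        payload = {
            "aggregate": {k: float(v) for k, v in self.aggregate.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "n_images": int(len(self.per_image)),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def evaluate_dataset(preds, truths, n_classes: int | None = None,
                     n_boot: int = 1000, seed: int = 0,
                     overlap_average: str = "foreground_mean") -> MetricReport:
    """Per-image NLL/Brier/Dice/Jaccard/recall/precision with bootstrap SEs.

    ``preds`` are probability maps, ``truths`` integer label masks.  Overlap
    metrics use the per-pixel argmax of each map; ``overlap_average`` selects
    whether the tabulated dice/jaccard/recall/precision are the mean over all
    classes (``"mean"``) or over foreground classes only (default).  Per-class
    values are kept in ``per_class``.
    """
    if len(preds) != len(truths):
        raise ShapeError(f"{len(preds)} predictions vs {len(truths)} truths")
    if overlap_average not in ("mean", "foreground_mean"):
        raise ParameterError(f"unknown overlap_average {overlap_average!r}")
    rows = []
    class_rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        p = np.asarray(p, dtype=np.float64)
        C = n_classes or p.shape[-1]
        t = as_label_mask(t)
        y = one_hot_encode(t, C)
        pred_mask = argmax_decode(p)
        ov = hard_overlap_metrics(pred_mask, t, C)
        rows.append({
            "image": i,
            "nll": nll(p, y),
            "brier": brier(p, y),
            "dice": ov[f"dice_{overlap_average}"] if overlap_average != "mean" else ov["dice_mean"],
            "jaccard": ov[f"jaccard_{overlap_average}"] if overlap_average != "mean" else ov["jaccard_mean"],
            "recall": ov[f"recall_{overlap_average}"] if overlap_average != "mean" else ov["recall_mean"],
            "precision": ov[f"precision_{overlap_average}"] if overlap_average != "mean" else ov["precision_mean"],
        })
        for c in range(C):
            class_rows.append({
                "image": i, "class": c,
                "dice": ov["dice"][c], "jaccard": ov["jaccard"][c],
                "recall": ov["recall"][c], "precision": ov["precision"][c],
            })
    per_image = pd.DataFrame(rows)
    aggregate = {m: float(per_image[m].mean()) for m in METRIC_COLUMNS}
    if len(per_image) >= 2:
        se = {m: bootstrap_se(per_image[m].to_numpy(), n_boot, seed)
              for m in METRIC_COLUMNS}
    else:
        se = {m: 0.0 for m in METRIC_COLUMNS}
    return MetricReport(per_image=per_image, aggregate=aggregate, se=se,
                        n_boot=n_boot, seed=seed,
                        per_class=pd.DataFrame(class_rows))
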