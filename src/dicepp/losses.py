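"""Dice-family and cross-entropy-family segmentation losses, with the DSC++
overconfidence penalty.

The central object is the DSC++ loss: the soft-Dice loss rewritten in terms of
per-class soft confusion sums, with a focal exponent ``gamma`` applied to each
per-pixel false-positive/false-negative probability product before summation::

    L_DSC++ = 1 - (1/C) sum_c  2*sum_i p0*y0
                               -----------------------------------------------
                               2*sum_i p0*y0 + sum_i (p0*y1)^g + sum_i (p1*y0)^g

Because every per-pixel error base lies in [0, 1], raising it to ``g > 1``
shrinks unconfident errors much faster than confident ones: the penalty is
selectively concentrated on confident, incorrect predictions, which is what
makes networks trained with it well calibrated.  At ``g = 1`` the loss is
exactly the soft-Dice loss.

Every Dice-based compound loss here (Tversky, Focal Tversky, Combo, Unified
Focal) accepts the same ``gamma_pp`` exponent on its FP/FN sums; the "++"
variant of each loss is the base loss with ``gamma_pp > 1``.  The exponent is
applied inside the sums, before any alpha/beta/delta weighting.

All formulas are written against the dispatch ops in :mod:`dicepp.autodiff`,
so the same code evaluates on plain numpy arrays (reference path) and on
autodiff ``Var`` nodes (differentiable path used for training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

from .autodiff import Var, clip, log, softmax, value_of, vsum
from .data import ParameterError, check_same_grid

#: probabilities are clipped to [CLIP_LO, 1 - CLIP_LO] before any log
CLIP_LO = 1e-7
#: default smoothing constant added to ratio numerators and denominators
SMOOTH_EPS = 1e-6


@dataclass
class LossConfig:
    """All loss hyperparameters, defaulting to the published settings.

    gamma_pp : DSC++ focal exponent on FP/FN sums (default 2; values in
        [0.5, 1) are permitted for grid searches, with a warning).
    focal_alpha / focal_gamma : Focal-loss class weight and exponent (0.5, 2).
    tversky_alpha / tversky_beta : FP and FN weights of the Tversky index
        (0.3, 0.7 — recall-favouring).
    ft_gamma : Focal-Tversky exponent; the loss is (1-TI)^(1/ft_gamma) (4/3).
    combo_alpha / combo_beta : Combo loss mixing weight and CE class weight
        (0.5, 0.5).
    uf_lambda / uf_delta / uf_gamma : Unified Focal mixing, asymmetry and
        focal parameters (0.5, 0.6, 0.5).
    smooth_eps : ratio smoothing constant.
    include_background : include class 0 in region-loss class sums/averages.
    rare_class : class id(s) treated as rare by the Unified Focal loss;
        None means every foreground class.
    """

    gamma_pp: float = 2.0
    focal_alpha: float | np.ndarray = 0.5
    focal_gamma: float = 2.0
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    ft_gamma: float = 4.0 / 3.0
    combo_alpha: float = 0.5
    combo_beta: float = 0.5
    uf_lambda: float = 0.5
    uf_delta: float = 0.6
    uf_gamma: float = 0.5
    smooth_eps: float = SMOOTH_EPS
    include_background: bool = True
    rare_class: int | tuple | None = None

    def replace(self, **kw) -> "LossConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path) -> "LossConfig":
        """Load from a YAML or JSON file whose keys mirror the field names;
        unknown keys raise."""
        import json

        import yaml

        with open(path) as fh:
            raw = (json.load(fh) if str(path).endswith(".json")
                   else yaml.safe_load(fh)) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ParameterError(f"unknown loss-config keys: {sorted(unknown)}")
        return cls(**raw)


def _prep(p, y):
    """Shape-check and return (p, y, n_pixels, n_classes); p may be a Var."""
    y = np.asarray(y, dtype=np.float64)
    pv = value_of(p)
    check_same_grid(pv, y)
    if not isinstance(p, Var):
        p = np.asarray(p, dtype=np.float64)
    C = y.shape[-1]
    N = int(np.prod(y.shape[:-1]))
    return p, y, N, C


def _class_weights(C: int, include_background: bool) -> np.ndarray:
    w = np.ones(C)
    if not include_background:
        w[0] = 0.0
    if w.sum() == 0:
        raise ParameterError("no classes left after background exclusion")
    return w


def _check_gamma_pp(gamma_pp: float) -> None:
    if gamma_pp <= 0:
        raise ParameterError(f"gamma_pp must be positive, got {gamma_pp}")
    if gamma_pp < 1:
        warnings.warn(
            f"gamma_pp={gamma_pp} < 1 softens, rather than sharpens, the error "
            "penalty; permitted for grid searches only",
            stacklevel=3,
        )


def _soft_terms(p, y, gamma_pp):
    """Per-class soft TP and gamma-exponentiated FP/FN sums (length-C vectors)."""
    spatial = tuple(range(y.ndim - 1))
    tp = vsum(p * y, axis=spatial)
    fp = vsum((p * (1.0 - y)) ** gamma_pp, axis=spatial)
    fn = vsum(((1.0 - p) * y) ** gamma_pp, axis=spatial)
    return tp, fp, fn


# --- cross-entropy family ---------------------------------------------------

def ce_loss(p, y):
    """Categorical cross entropy, -(1/N) sum_i sum_c y*log(p)."""
    p, y, N, _ = _prep(p, y)
    pc = clip(p, CLIP_LO, 1.0 - CLIP_LO)
    return -vsum(y * log(pc)) / N


def focal_loss(p, y, alpha=0.5, gamma: float = 2.0):
    """Focal loss: alpha_c * (1 - p_t)^gamma * (-log p_t), averaged over pixels.

    ``p_t`` is the probability assigned to the true class; at ``gamma=0`` this
    is the alpha-weighted cross entropy.
    """
    if gamma < 0:
        raise ParameterError(f"focal gamma must be >= 0, got {gamma}")
    p, y, N, C = _prep(p, y)
    a = np.asarray(alpha, dtype=np.float64)
    if a.ndim == 1 and a.shape[0] != C:
        raise ParameterError(f"focal alpha vector length {a.shape[0]} != C={C}")
    pc = clip(p, CLIP_LO, 1.0 - CLIP_LO)
    return -vsum(a * y * (1.0 - pc) ** gamma * log(pc)) / N


# --- Dice family ------------------------------------------------------------

def dscpp_loss(p, y, gamma_pp: float = 2.0, eps: float = SMOOTH_EPS,
               include_background: bool = True):
    """DSC++ loss; at ``gamma_pp=1`` exactly the soft-Dice loss.

    Averages ``1 - (2 TP + eps) / (2 TP + FP^g + FN^g + eps)`` over the
    included classes, so the value lies in [0, 1].
    """
    _check_gamma_pp(gamma_pp)
    p, y, _, C = _prep(p, y)
    w = _class_weights(C, include_background)
    tp, fp, fn = _soft_terms(p, y, gamma_pp)
    dsc_c = (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)
    return 1.0 - vsum(w * dsc_c) / w.sum()


def tversky_loss(p, y, alpha: float = 0.3, beta: float = 0.7,
                 gamma_pp: float = 1.0, eps: float = SMOOTH_EPS,
                 include_background: bool = True, factor2: bool = False):
    """Tversky loss, sum_c (1 - TI_c) with TI = TP / (TP + a*FP^g + b*FN^g).

    ``alpha``/``beta`` trade false-positive against false-negative weight;
    ``gamma_pp`` is the ++ exponent on the FP/FN sums.  Summed over classes
    (no 1/C), so the range is [0, C].  ``factor2=True`` switches the ratio to
    the Dice convention (2 TP numerator, weights doubled), making
    ``alpha=beta=0.5`` reproduce the per-class DSC ratio including smoothing.
    """
    if alpha < 0 or beta < 0:
        raise ParameterError("tversky alpha/beta must be non-negative")
    if alpha == 0 and beta == 0:
        raise ParameterError("tversky alpha and beta cannot both be zero")
    _check_gamma_pp(gamma_pp)
    p, y, _, C = _prep(p, y)
    w = _class_weights(C, include_background)
    tp, fp, fn = _soft_terms(p, y, gamma_pp)
    if factor2:
        ti = (2.0 * tp + eps) / (2.0 * tp + 2.0 * alpha * fp + 2.0 * beta * fn + eps)
    else:
        ti = (tp + eps) / (tp + alpha * fp + beta * fn + eps)
    return vsum(w * (1.0 - ti))


def focal_tversky_loss(p, y, alpha: float = 0.3, beta: float = 0.7,
                       ft_gamma: float = 4.0 / 3.0, gamma_pp: float = 1.0,
                       eps: float = SMOOTH_EPS, include_background: bool = True):
    """Focal Tversky loss, sum_c (1 - TI_c)^(1/ft_gamma).

    ``ft_gamma > 1`` (exponent < 1) focuses on poorly segmented classes;
    ``ft_gamma=1`` recovers the Tversky loss.
    """
    if ft_gamma <= 0:
        raise ParameterError(f"ft_gamma must be > 0, got {ft_gamma}")
    if alpha == 0 and beta == 0:
        raise ParameterError("tversky alpha and beta cannot both be zero")
    _check_gamma_pp(gamma_pp)
    p, y, _, C = _prep(p, y)
    w = _class_weights(C, include_background)
    tp, fp, fn = _soft_terms(p, y, gamma_pp)
    ti = (tp + eps) / (tp + alpha * fp + beta * fn + eps)
    return vsum(w * (1.0 - ti) ** (1.0 / ft_gamma))


def combo_loss(p, y, combo_alpha: float = 0.5, combo_beta: float = 0.5,
               gamma_pp: float = 1.0, eps: float = SMOOTH_EPS,
               include_background: bool = True):
    """Combo loss: alpha * mCE - (1 - alpha) * DSC_score.

    The modified cross entropy weights the positive-class log term by ``beta``
    and the negative-class term by ``1 - beta``, with the overall -1/N factor
    distributed over both terms; it is computed over foreground channels (over
    all channels the beta weighting cancels algebraically for binary maps).
    ``DSC_score = 1 - dscpp_loss(gamma_pp)``, so ``gamma_pp=1`` is the
    original Combo loss.  The value can be negative (the -DSC term).
    """
    if not (0 <= combo_alpha <= 1 and 0 <= combo_beta <= 1):
        raise ParameterError("combo alpha/beta must lie in [0, 1]")
    p, y, N, C = _prep(p, y)
    wfg = np.zeros(C)
    wfg[1:] = 1.0
    pc = clip(p, CLIP_LO, 1.0 - CLIP_LO)
    mce = -vsum(
        wfg * (combo_beta * y * log(pc) + (1.0 - combo_beta) * (1.0 - y) * log(1.0 - pc))
    ) / N
    dsc_score = 1.0 - dscpp_loss(p, y, gamma_pp, eps, include_background)
    return combo_alpha * mce - (1.0 - combo_alpha) * dsc_score


def unified_focal_loss(p, y, uf_lambda: float = 0.5, uf_delta: float = 0.6,
                       uf_gamma: float = 0.5, gamma_pp: float = 1.0,
                       eps: float = SMOOTH_EPS, rare_class=None):
    """Unified Focal loss: lambda * L_AF + (1 - lambda) * L_AFT.

    The asymmetric Focal component gives rare-class pixels a plain
    delta-weighted CE term and other pixels a (1-delta)-weighted focal CE
    term.  The asymmetric Focal-Tversky component uses a Tversky index with
    weights (1-delta) on FP and delta on FN, applying the focusing exponent
    ``1 - uf_gamma`` only to rare classes.  ``gamma_pp`` exponentiates the
    FP/FN sums inside the index for the ++ variant.  ``rare_class`` may be an
    int, an iterable of ints, or None (every foreground class).
    """
    if not (0 <= uf_lambda <= 1 and 0 <= uf_delta <= 1):
        raise ParameterError("uf_lambda/uf_delta must lie in [0, 1]")
    if not (0 < uf_gamma < 1):
        raise ParameterError(
            f"uf_gamma must lie in (0, 1) for the 1-gamma exponent, got {uf_gamma}"
        )
    _check_gamma_pp(gamma_pp)
    p, y, N, C = _prep(p, y)
    if rare_class is None:
        rare = list(range(1, C))
    elif np.isscalar(rare_class):
        rare = [int(rare_class)]
    else:
        rare = [int(r) for r in rare_class]
    if any(r < 0 or r >= C for r in rare):
        raise ParameterError(f"rare_class {rare} outside [0, {C - 1}]")
    rare_w = np.zeros(C)
    rare_w[rare] = 1.0
    nonrare_w = 1.0 - rare_w

    pc = clip(p, CLIP_LO, 1.0 - CLIP_LO)
    l_af = (
        -uf_delta / N * vsum(rare_w * y * log(pc))
        - (1.0 - uf_delta) / N * vsum(nonrare_w * y * (1.0 - pc) ** uf_gamma * log(pc))
    )
    tp, fp, fn = _soft_terms(p, y, gamma_pp)
    ti = (tp + eps) / (tp + (1.0 - uf_delta) * fp + uf_delta * fn + eps)
    l_aft = vsum(nonrare_w * (1.0 - ti)) + vsum(rare_w * (1.0 - ti) ** (1.0 - uf_gamma))
    return uf_lambda * l_af + (1.0 - uf_lambda) * l_aft


# --- registry ---------------------------------------------------------------

def _reg_ce(p, y, cfg):
    return ce_loss(p, y)


def _reg_focal(p, y, cfg):
    return focal_loss(p, y, cfg.focal_alpha, cfg.focal_gamma)


def _reg_dsc(p, y, cfg, pp=False):
    return dscpp_loss(p, y, cfg.gamma_pp if pp else 1.0, cfg.smooth_eps,
                      cfg.include_background)


def _reg_tversky(p, y, cfg, pp=False):
    return tversky_loss(p, y, cfg.tversky_alpha, cfg.tversky_beta,
                        cfg.gamma_pp if pp else 1.0, cfg.smooth_eps,
                        cfg.include_background)


def _reg_focal_tversky(p, y, cfg, pp=False):
    return focal_tversky_loss(p, y, cfg.tversky_alpha, cfg.tversky_beta,
                              cfg.ft_gamma, cfg.gamma_pp if pp else 1.0,
                              cfg.smooth_eps, cfg.include_background)


def _reg_combo(p, y, cfg, pp=False):
    return combo_loss(p, y, cfg.combo_alpha, cfg.combo_beta,
                      cfg.gamma_pp if pp else 1.0, cfg.smooth_eps,
                      cfg.include_background)


def _reg_unified_focal(p, y, cfg, pp=False):
    return unified_focal_loss(p, y, cfg.uf_lambda, cfg.uf_delta, cfg.uf_gamma,
                              cfg.gamma_pp if pp else 1.0, cfg.smooth_eps,
                              cfg.rare_class)


LOSS_REGISTRY = {
    "ce": _reg_ce,
    "focal": _reg_focal,
    "dsc": lambda p, y, cfg: _reg_dsc(p, y, cfg, pp=False),
    "dsc++": lambda p, y, cfg: _reg_dsc(p, y, cfg, pp=True),
    "tversky": lambda p, y, cfg: _reg_tversky(p, y, cfg, pp=False),
    "tversky++": lambda p, y, cfg: _reg_tversky(p, y, cfg, pp=True),
    "focal_tversky": lambda p, y, cfg: _reg_focal_tversky(p, y, cfg, pp=False),
    "focal_tversky++": lambda p, y, cfg: _reg_focal_tversky(p, y, cfg, pp=True),
    "combo": lambda p, y, cfg: _reg_combo(p, y, cfg, pp=False),
    "combo++": lambda p, y, cfg: _reg_combo(p, y, cfg, pp=True),
    "unified_focal": lambda p, y, cfg: _reg_unified_focal(p, y, cfg, pp=False),
    "unified_focal++": lambda p, y, cfg: _reg_unified_focal(p, y, cfg, pp=True),
}


def get_loss(name: str):
    """Look up a registered loss by name; callable as fn(p, y, cfg) -> loss."""
    try:
        return LOSS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown loss {name!r}; registered: {sorted(LOSS_REGISTRY)}"
        ) from None


def loss_value(name: str, p, y, cfg: LossConfig | None = None) -> float:
    """Evaluate a registered loss on numpy arrays (reference path)."""
    cfg = cfg or LossConfig()
    return float(value_of(get_loss(name)(p, y, cfg)))


def loss_gradient(name: str, p, y, cfg: LossConfig | None = None):
    """Loss value and gradient w.r.t. the raw probability entries."""
    cfg = cfg or LossConfig()
    v = Var(np.asarray(p, dtype=np.float64))
    out = get_loss(name)(v, y, cfg)
    out.backward()
    return float(out.value), v.grad


def loss_gradient_logits(name: str, z, y, cfg: LossConfig | None = None):
    """Loss value and gradient w.r.t. pre-softmax logits (training path)."""
    cfg = cfg or LossConfig()
    zv = Var(np.asarray(z, dtype=np.float64))
    out = get_loss(name)(softmax(zv), y, cfg)
    out.backward()
    return float(out.value), zv.grad


def numerical_gradient(name: str, p, y, cfg: LossConfig | None = None,
                       h: float = 1e-5) -> np.ndarray:
    """Central-finite-difference gradient of a reference loss w.r.t. each raw
    probability entry (no renormalisation of the perturbed map).

    Oracle for the differentiable path; O(2 * p.size) loss evaluations, so use
    small inputs.
    """
    if not (0 < h <= 1e-3):
        raise ParameterError(f"step h must lie in (0, 1e-3], got {h}")
    cfg = cfg or LossConfig()
    fn = get_loss(name)
    p = np.array(p, dtype=np.float64)
    grad = np.zeros_like(p)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = p[idx]
        p[idx] = orig + h
        hi = float(value_of(fn(p, y, cfg)))
        p[idx] = orig - h
        lo = float(value_of(fn(p, y, cfg)))
        p[idx] = orig
        grad[idx] = (hi - lo) / (2.0 * h)
    return grad
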