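"""Worked examples, identity ladder, loop oracles and the overconfidence
penalty mechanism for every loss in the registry."""

import numpy as np
import pytest

from dicepp.data import ParameterError
from dicepp.losses import (
    LOSS_REGISTRY,
    CLIP_LO,
    LossConfig,
    ce_loss,
    combo_loss,
    dscpp_loss,
    focal_loss,
    focal_tversky_loss,
    loss_value,
    tversky_loss,
    unified_focal_loss,
)
from tests.conftest import random_one_hot, random_prob_map

# ---------------------------------------------------------------------------
# independent oracles (naive implementations, kept free of package internals)
# ---------------------------------------------------------------------------


def dsc_loss_oracle(p, y, eps=0.0):
    """Soft-Dice loss from the ratio-of-sums form: per class,
    2*sum(p*y) / (sum(p) + sum(y)), averaged over classes."""
    C = y.shape[-1]
    pf, yf = p.reshape(-1, C), y.reshape(-1, C)
    vals = [
        (2 * (pf[:, c] * yf[:, c]).sum() + eps)
        / (pf[:, c].sum() + yf[:, c].sum() + eps)
        for c in range(C)
    ]
    return 1.0 - float(np.mean(vals))


def _loop_confusion(p, y, gamma):
    C = y.shape[-1]
    pf, yf = p.reshape(-1, C), y.reshape(-1, C)
    tp = np.zeros(C)
    fp = np.zeros(C)
    fn = np.zeros(C)
    for i in range(pf.shape[0]):
        for c in range(C):
            tp[c] += pf[i, c] * yf[i, c]
            fp[c] += (pf[i, c] * (1 - yf[i, c])) ** gamma
            fn[c] += ((1 - pf[i, c]) * yf[i, c]) ** gamma
    return tp, fp, fn


def loop_oracle(name, p, y, cfg):
    """Per-pixel double-loop evaluation of each registered loss."""
    C = y.shape[-1]
    pf = np.clip(p.reshape(-1, C), CLIP_LO, 1 - CLIP_LO)
    yf = y.reshape(-1, C)
    N = pf.shape[0]
    eps = cfg.smooth_eps
    g_pp = cfg.gamma_pp if name.endswith("++") else 1.0

    if name == "ce":
        return -sum(yf[i, c] * np.log(pf[i, c])
                    for i in range(N) for c in range(C)) / N
    if name == "focal":
        return -sum(cfg.focal_alpha * yf[i, c]
                    * (1 - pf[i, c]) ** cfg.focal_gamma * np.log(pf[i, c])
                    for i in range(N) for c in range(C)) / N

    tp, fp, fn = _loop_confusion(p.reshape(-1, C), yf, g_pp)
    if name in ("dsc", "dsc++"):
        ratios = [(2 * tp[c] + eps) / (2 * tp[c] + fp[c] + fn[c] + eps)
                  for c in range(C)]
        return 1.0 - float(np.mean(ratios))
    if name in ("tversky", "tversky++", "focal_tversky", "focal_tversky++"):
        a, b = cfg.tversky_alpha, cfg.tversky_beta
        ti = [(tp[c] + eps) / (tp[c] + a * fp[c] + b * fn[c] + eps)
              for c in range(C)]
        if name.startswith("focal"):
            return float(sum((1 - t) ** (1 / cfg.ft_gamma) for t in ti))
        return float(sum(1 - t for t in ti))
    if name in ("combo", "combo++"):
        b = cfg.combo_beta
        mce = -sum(b * yf[i, c] * np.log(pf[i, c])
                   + (1 - b) * (1 - yf[i, c]) * np.log(1 - pf[i, c])
                   for i in range(N) for c in range(1, C)) / N
        ratios = [(2 * tp[c] + eps) / (2 * tp[c] + fp[c] + fn[c] + eps)
                  for c in range(C)]
        score = float(np.mean(ratios))
        return cfg.combo_alpha * mce - (1 - cfg.combo_alpha) * score
    if name in ("unified_focal", "unified_focal++"):
        d, lam, g = cfg.uf_delta, cfg.uf_lambda, cfg.uf_gamma
        rare = set(range(1, C))
        af = 0.0
        for i in range(N):
            c = int(np.argmax(yf[i]))
            if c in rare:
                af += -d * np.log(pf[i, c])
            else:
                af += -(1 - d) * (1 - pf[i, c]) ** g * np.log(pf[i, c])
        af /= N
        ti = [(tp[c] + eps) / (tp[c] + (1 - d) * fp[c] + d * fn[c] + eps)
              for c in range(C)]
        aft = sum((1 - ti[c]) ** (1 - g) if c in rare else 1 - ti[c]
                  for c in range(C))
        return lam * af + (1 - lam) * aft
    raise KeyError(name)


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


class TestWorkedExamples:
    def test_ce(self, four_pixel_case, rng):
        p, y = four_pixel_case
        assert ce_loss(y, y) <= 1.2e-7  # clip floor
        uniform = np.full((2, 2, 2), 0.5)
        assert ce_loss(uniform, y) == pytest.approx(np.log(2), abs=1e-12)
        p2 = np.array([[[0.9, 0.1], [0.4, 0.6]]])
        y2 = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        assert ce_loss(p2, y2) == pytest.approx(0.308090, abs=1e-5)

    def test_focal_single_pixel(self):
        p = np.array([[[0.5, 0.5]]])
        y = np.array([[[1.0, 0.0]]])
        assert focal_loss(p, y, alpha=0.5, gamma=2.0) == pytest.approx(
            0.086643, abs=1e-5)
        assert focal_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_dsc_and_dscpp_four_pixel(self, four_pixel_case):
        """gamma=1 gives the soft-Dice value 0.25; gamma=2 shrinks the
        unconfident 0.5-errors to 0.25 each, giving 1 - 3/3.5."""
        p, y = four_pixel_case
        kw = dict(eps=0.0, include_background=False)
        assert dscpp_loss(p, y, 1.0, **kw) == pytest.approx(0.25, abs=1e-12)
        assert dscpp_loss(p, y, 2.0, **kw) == pytest.approx(1 - 3.0 / 3.5, abs=1e-12)
        # with the default smoothing the values move by less than 1e-5
        assert dscpp_loss(p, y, 2.0, include_background=False) == pytest.approx(
            0.142857, abs=1e-5)

    def test_tversky_four_pixel(self, four_pixel_case):
        p, y = four_pixel_case
        kw = dict(eps=0.0, include_background=False)
        assert tversky_loss(p, y, 0.3, 0.7, 1.0, **kw) == pytest.approx(0.25, abs=1e-12)
        assert tversky_loss(p, y, 0.3, 0.7, 2.0, **kw) == pytest.approx(
            1 - 1.5 / 1.75, abs=1e-12)
        assert tversky_loss(y, y, 0.4, 0.6) == pytest.approx(0.0, abs=1e-5)

    def test_focal_tversky_four_pixel(self, four_pixel_case):
        p, y = four_pixel_case
        got = focal_tversky_loss(p, y, 0.3, 0.7, ft_gamma=4 / 3, gamma_pp=1.0,
                                 eps=0.0, include_background=False)
        assert got == pytest.approx(0.25**0.75, abs=1e-12)
        assert got == pytest.approx(0.353553, abs=1e-5)
        assert focal_tversky_loss(y, y, 0.3, 0.7) == pytest.approx(0.0, abs=1e-4)

    def test_combo_perfect_prediction(self, rng):
        y = random_one_hot(rng, (6, 6), 2)
        assert combo_loss(y, y, combo_alpha=0.5) == pytest.approx(-0.5, abs=1e-5)

    def test_unified_focal_perfect_prediction(self, rng):
        y = random_one_hot(rng, (6, 6), 2)
        assert unified_focal_loss(y, y) == pytest.approx(0.0, abs=1e-5)


# ---------------------------------------------------------------------------
# identity ladder
# ---------------------------------------------------------------------------


class TestIdentityLadder:
    N_RANDOM = 50

    def _random_pair(self, rng, C=2):
        shape = (6, 6) if rng.random() < 0.7 else (3, 4, 4)
        return (random_prob_map(rng, shape, C), random_one_hot(rng, shape, C))

    def test_dscpp_gamma1_is_dsc(self, rng):
        """At gamma=1 the DSC++ loss is identical to the soft-Dice loss
        computed independently from the ratio-of-sums form."""
        for _ in range(self.N_RANDOM):
            C = int(rng.integers(2, 4))
            p, y = self._random_pair(rng, C)
            got = dscpp_loss(p, y, gamma_pp=1.0, eps=1e-6)
            want = dsc_loss_oracle(p, y, eps=1e-6)
            assert got == pytest.approx(want, abs=1e-12)

    def test_focal_gamma0_alpha1_is_ce(self, rng):
        for _ in range(self.N_RANDOM):
            p, y = self._random_pair(rng)
            assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(
                ce_loss(p, y), abs=1e-12)

    def test_focal_tversky_gamma1_is_tversky(self, rng):
        for _ in range(self.N_RANDOM):
            p, y = self._random_pair(rng)
            assert focal_tversky_loss(p, y, 0.3, 0.7, ft_gamma=1.0) == pytest.approx(
                tversky_loss(p, y, 0.3, 0.7), abs=1e-12)

    def test_tversky_half_half_factor2_is_dsc(self, rng):
        """alpha=beta=0.5 with the Dice ratio convention reproduces the DSC
        loss per class (the Tversky sum equals C times the Dice average)."""
        for _ in range(self.N_RANDOM):
            C = int(rng.integers(2, 4))
            p, y = self._random_pair(rng, C)
            tv = tversky_loss(p, y, 0.5, 0.5, factor2=True)
            assert tv / C == pytest.approx(dscpp_loss(p, y, 1.0), abs=1e-12)

    def test_combo_alpha1_is_mce(self, rng):
        cfg = LossConfig(combo_alpha=1.0)
        for _ in range(self.N_RANDOM):
            p, y = self._random_pair(rng)
            got = combo_loss(p, y, combo_alpha=1.0, combo_beta=cfg.combo_beta)
            # beta=0.5 halves the standard foreground-channel binary CE
            pc = np.clip(p, CLIP_LO, 1 - CLIP_LO)
            bce = -np.mean(y[..., 1] * np.log(pc[..., 1])
                           + (1 - y[..., 1]) * np.log(1 - pc[..., 1]))
            assert got == pytest.approx(0.5 * bce, abs=1e-12)

    def test_unified_focal_endpoints_and_linearity(self, rng):
        for _ in range(self.N_RANDOM):
            p, y = self._random_pair(rng)
            u0 = unified_focal_loss(p, y, uf_lambda=0.0)
            u1 = unified_focal_loss(p, y, uf_lambda=1.0)
            mid = unified_focal_loss(p, y, uf_lambda=0.3)
            assert mid == pytest.approx(0.3 * u1 + 0.7 * u0, abs=1e-12)


# ---------------------------------------------------------------------------
# loop oracles
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", sorted(LOSS_REGISTRY))
@pytest.mark.parametrize("shape,C", [((8, 8), 2), ((4, 8, 8), 3)])
def test_vectorised_matches_loop_oracle(name, shape, C, rng):
    """Every registered loss agrees with a naive per-pixel loop."""
    cfg = LossConfig()
    p = random_prob_map(rng, shape, C)
    y = random_one_hot(rng, shape, C)
    got = loss_value(name, p, y, cfg)
    want = loop_oracle(name, p, y, cfg)
    assert got == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------------------------
# the overconfidence penalty mechanism
# ---------------------------------------------------------------------------


def _single_error_map(q, n_pixels=16):
    """Binary map: all pixels perfectly predicted except one background pixel
    assigned to the foreground with confidence q."""
    mask = np.zeros(n_pixels, dtype=int)
    mask[: n_pixels // 4] = 1
    y = np.stack([1.0 - mask, mask * 1.0], axis=-1).reshape(4, -1, 2)
    p = y.copy()
    err = n_pixels // 4  # a background pixel
    flat = p.reshape(-1, 2)
    flat[err] = [1 - q, q]
    return p, y


class TestPenaltyMechanism:
    def test_error_term_decreasing_in_gamma(self):
        for q in (0.1, 0.5, 0.9, 0.99):
            gammas = np.linspace(1.0, 5.0, 9)
            terms = q**gammas
            assert np.all(np.diff(terms) < 0)

    def test_loss_non_increasing_in_gamma(self):
        for q in (0.3, 0.6, 0.99):
            p, y = _single_error_map(q)
            gammas = [1.0, 1.5, 2.0, 3.0, 4.0]
            vals = [dscpp_loss(p, y, g) for g in gammas]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_confident_error_relative_penalty_grows(self):
        """The ratio loss(confident error) / loss(unconfident error) increases
        with gamma: the penalty is selectively aimed at confident mistakes."""
        p_conf, y = _single_error_map(0.99)
        p_unconf, _ = _single_error_map(0.5)
        ratios = []
        for g in (1.0, 2.0, 3.0, 4.0):
            ratios.append(dscpp_loss(p_conf, y, g) / dscpp_loss(p_unconf, y, g))
        assert np.all(np.diff(ratios) > 0)


# ---------------------------------------------------------------------------
# bounds, degenerate inputs, parameter errors
# ---------------------------------------------------------------------------


class TestBoundsAndErrors:
    def test_region_losses_at_perfect_and_inverted(self, rng):
        y = random_one_hot(rng, (6, 6), 2)
        inv = 1.0 - y
        eps_tol = 2e-6
        assert dscpp_loss(y, y) <= eps_tol
        assert tversky_loss(y, y) <= eps_tol
        assert focal_tversky_loss(y, y) <= 2e-4  # (eps-ratio)^(3/4)
        assert dscpp_loss(inv, y) == pytest.approx(1.0, abs=1e-4)
        assert tversky_loss(inv, y) == pytest.approx(2.0, abs=1e-4)

    def test_gamma_below_one_warns(self, four_pixel_case):
        p, y = four_pixel_case
        with pytest.warns(UserWarning, match="gamma_pp"):
            dscpp_loss(p, y, gamma_pp=0.5)

    def test_parameter_errors(self, four_pixel_case):
        p, y = four_pixel_case
        with pytest.raises(ParameterError):
            tversky_loss(p, y, 0.0, 0.0)
        with pytest.raises(ParameterError):
            focal_loss(p, y, alpha=np.array([1.0, 1.0, 1.0]))  # wrong length
        with pytest.raises(ParameterError):
            unified_focal_loss(p, y, rare_class=5)
        with pytest.raises(ParameterError):
            unified_focal_loss(p, y, uf_gamma=1.5)

    def test_defaults_match_published_settings(self):
        cfg = LossConfig()
        assert (cfg.focal_alpha, cfg.focal_gamma) == (0.5, 2)
        assert (cfg.tversky_alpha, cfg.tversky_beta) == (0.3, 0.7)
        assert cfg.ft_gamma == pytest.approx(4 / 3)
        assert (cfg.combo_alpha, cfg.combo_beta) == (0.5, 0.5)
        assert (cfg.uf_gamma, cfg.uf_delta, cfg.uf_lambda) == (0.5, 0.6, 0.5)
        assert cfg.gamma_pp == 2
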