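# Methods

## The problem

Pixel-wise segmentation networks for biomedical images are usually trained
with either a distribution-based loss (cross entropy and variants) or a
region-based loss (the soft-Dice family). The two families fail in
complementary ways: cross entropy is well calibrated but under-segments small
structures under class imbalance, while the soft-Dice loss is robust to
imbalance but drives the softmax outputs to the extremes, producing
confidently wrong probabilities that cannot be read as uncertainty. This
package implements the calibration-aware extension of the Dice family — the
DSC++ loss — together with the metrics, post-processing and experiment
machinery needed to study it end to end on synthetic data.

## The DSC++ loss

Write the soft-Dice loss per class c in terms of per-pixel probability
products, with `p0 = p_{i,c}` the predicted probability of class c at pixel
i, `p1 = 1 − p0`, and `y0, y1` the one-hot indicator and its complement:

    L_DSC = 1 − (1/C) Σ_c  2 Σ_i p0·y0
                           ───────────────────────────────────
                           2 Σ_i p0·y0 + Σ_i p0·y1 + Σ_i p1·y0

The two error sums are the soft false positives and false negatives. The
DSC++ loss raises each per-pixel error *product* to a focal exponent γ
before summation: `Σ (p0·y1)^γ + Σ (p1·y0)^γ`. Every base lies in [0, 1],
so for γ > 1 an unconfident error (product near 0.5) shrinks much faster
than a confident one (product near 1): the penalty is selectively
concentrated on confident, incorrect predictions. At γ = 1 the loss is
exactly the soft-Dice loss; γ = 2 is the default.

The same exponent slots into every Dice-based compound loss. Each "++"
variant here is the base loss with `gamma_pp > 1` applied to its FP/FN sums,
with the exponent always inside the sum and applied before any α/β/δ
weighting:

- **Tversky**: `Σ_c (1 − TI_c)`, `TI = TP / (TP + α·FP^γ + β·FN^γ)`
  (α = 0.3, β = 0.7; summed over classes, range [0, C]).
- **Focal Tversky**: `Σ_c (1 − TI_c)^(1/γ_ft)`, γ_ft = 4/3.
- **Combo**: `α·mCE − (1−α)·(1 − L_DSC++)` with a β-weighted modified cross
  entropy (α = β = 0.5).
- **Unified Focal**: `λ·L_AF + (1−λ)·L_AFT` (λ = 0.5, δ = 0.6, γ = 0.5),
  combining an asymmetric focal CE term with an asymmetric focal-Tversky
  term whose index weights FP by 1−δ and FN by δ.

Cross entropy and the Focal loss (α = 0.5, γ = 2) complete the registry.
All defaults are the settings published for these losses; the γ grid-search
helper defaults to γ ∈ [0.5, 5] in steps of 0.5.

### Reading choices for ambiguous formulas

Several of the printed formulas in the loss literature are ambiguous or
internally inconsistent; the conventions adopted here are:

- **Modified CE (Combo)**: the leading −1/N distributes over both the β and
  (1−β) terms (any other reading is unbounded below), and the term is
  computed over foreground channels only — over all channels the β weighting
  cancels algebraically for binary maps, which would make β inert.
- **Asymmetric focal CE (Unified Focal)**: pixels whose true class is rare
  contribute a plain δ-weighted CE term; all other pixels contribute a
  (1−δ)-weighted `(1 − p_t)^γ · (−log p_t)` focal term. `rare_class`
  defaults to every foreground class.
- **Focal loss**: implemented exactly as the standard formula, which reduces
  to weighted CE at γ = 0 (not γ = 1, as is sometimes stated).
- **Softmax thresholding**: foreground ⇔ `s ≥ T`. The literal indicator
  `s < T` contradicts both the argmax equivalence at T = 0.5 and the stated
  behaviour that higher thresholds favour precision. Ties (`s == T`) go to
  the foreground.
- **Brier score**: mean of `(y − p)²` over all N·C entries.

### Numerical choices

- Ratio smoothing: ε = 1e-6 added to every numerator and denominator
  (TI, Dice). This prevents 0/0 on empty classes and moves the worked
  examples by less than 1e-5.
- Probabilities are clipped to [1e-7, 1−1e-7] before any logarithm, which
  bounds NLL at ≈16.1 per pixel.
- `0^γ` is defined as 0 for all γ > 0 (continuous extension), so exact-zero
  error products do not produce NaNs.
- Argmax ties resolve to the lowest class index everywhere.
- Per-pixel probability sums must be within 1e-6 of 1; renormalisation is
  opt-in, never silent.
- Class averaging: the Dice family averages over all C classes by default
  (`include_background=False` is available); the Tversky family sums over
  classes as printed, so its range is [0, C]. The worked-example tests state
  which convention they use.

## Differentiable path

Gradients come from a minimal reverse-mode autodiff over numpy arrays
(`dicepp.autodiff`): elementwise arithmetic, constant powers, log/exp,
broadcasting-aware sums, and a pass-through clip. The loss formulas are
written once against a dispatch layer and evaluate identically on plain
arrays and autodiff nodes, so the reference and differentiable paths cannot
drift. Training differentiates through the softmax to the logits. Every
registered loss is checked against a central-finite-difference oracle
(h = 1e-5, max relative error ≤ 1e-4 on interior points; observed ~1e-9).

## Synthetic data

The generator produces the class-imbalance regimes the loss family targets,
at desk scale (default 200 images of 64×64, 5% foreground, Gaussian noise
sd 0.3 on a ~0.6 intensity contrast):

- **vessel**: a random-walk trunk with branches rooted on already-drawn
  pixels, dilated to width 1–3 px — thin, connected, curvilinear foreground
  (the realised fraction is steered onto the target during drawing);
- **blob**: a smoothed Gaussian random field thresholded at the matching
  quantile — compact lesion/nucleus-like shapes;
- **multiclass-organ**: a smooth organ ellipse (class 1) containing a
  smaller lesion (class 2).

Per-image target fractions are jittered by a clipped log-normal (±20%) so
every image stays within ±50% of the configured fraction. All generation is
deterministic given the seed.

`simulate_predictor` emulates a trained model's softmax output: a softmax
over per-class signed boundary distances scaled by τ (graded uncertainty at
boundaries, confidence inside regions). Label errors are placed only inside
the uncertain band, at a per-pixel rate proportional to the local
uncertainty, and the reported confidence there is reset to 1 − (local error
rate) — so the k = 1 map is *calibrated by construction*: its confidence
matches its correctness probability, the way real networks err on the
structures they are unsure of. The sharpening exponent k (p^k, renormalised)
then reproduces the overconfident failure mode: it changes no argmax, so
overlap metrics are untouched, while both proper scores strictly degrade.

What the simulator does **not** capture: correlated error structure from a
real network's receptive field, systematic boundary bias, intensity-driven
confusions, or out-of-distribution behaviour. Tests passing on it show the
metrics and post-processing respond correctly to confidence structure, not
that any real model is calibrated.

Augmentation follows the standard recipe (probability 0.15 per sample; one
of scaling 0.85–1.25×, rotation ±15°, mirroring, elastic deformation with
α ∈ [0, 900], σ ∈ [9, 13], brightness 0.5–2×), with nearest-neighbour
resampling on masks. Patch sampling enumerates the stride grid implied by
the requested overlap, with end-aligned origins so the grid covers the
volume.

## Trainer and experiment harness

The trainer is a pure-numpy two-level U-Net (3×3 convolutions, instance
normalisation, ReLU, 2× max-pool, nearest-neighbour upsampling with skip
concatenation, 1×1 output head; Xavier init; 8 base filters by default),
wrapped as a scikit-learn estimator (`TinyUNetSegmenter`). Optimisation is
plain SGD at batch size 1 with initial learning rate 0.1,
reduce-LR-on-plateau (×0.1) and early stopping on the validation loss
(patiences 25/50 by default). Splits are 80/20 development/test with the
development set split 80/20 again (100 images → 64/16/20), deterministic
given the seed.

Problem sizes for the shipped experiments are a deliberate desk-scale
choice: 200 images of 64×64, 12-epoch cap, 3 seeds. At this scale one full
γ ∈ {1, 2} comparison across three seeds runs in a few minutes on one CPU
and already reproduces the qualitative result: the median test NLL roughly
halves at γ = 2 while the median Dice moves by well under 0.05. Only the
direction of this effect is claimed, never the magnitudes of the original
GPU-scale experiments; training is tagged stochastic and all training-based
checks use medians over ≥3 seeds.

## Known limitations

- The trainer is 2D; 3D data is supported by the losses, metrics, generator
  and patch sampler, but not by the bundled network.
- The Tversky-family range [0, C] and the possibly negative Combo loss
  follow the printed conventions; consumers comparing loss values across
  families must account for the differing scales.
- Bootstrap SEs and CIs resample images, not pixels; with few images they
  are themselves noisy.
- The autodiff layer supports exactly the operations the losses need; it is
  not a general-purpose framework.
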