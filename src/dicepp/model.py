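"""Tiny U-Net segmentation model in pure numpy, with a scikit-learn style
estimator wrapper.

The network is a two-level U-Net (two 3x3 conv + instance-norm + ReLU blocks
per level, 2x max-pool down, nearest-neighbour up with skip concatenation,
1x1 output conv), Xavier-initialised and trained with plain SGD at batch size
1.  Forward and backward passes are hand-written im2col convolutions; the
loss gradient with respect to the logits comes from the autodiff path in
:mod:`dicepp.losses`, so any registered loss can drive training.

This is deliberately small: at 64x64 with 8 base filters a full train/eval
cycle runs in seconds on one CPU, which is what makes desk-scale, seeded
experiments on the loss functions practical.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import ParameterError, one_hot_encode
from .losses import LossConfig, get_loss, loss_gradient_logits, loss_value


def _xavier(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Conv2D:
    """3x3 (or 1x1) same-padding convolution on (C, H, W) arrays."""

    def __init__(self, rng, c_in, c_out, k=3):
        self.k = k
        fan = c_in * k * k
        self.W = _xavier(rng, fan, c_out * k * k, (c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self._cache = None

    def forward(self, x):
        k = self.k
        pad = k // 2
        c_in, H, W = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = win.transpose(1, 2, 0, 3, 4).reshape(H * W, c_in * k * k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (cols, x.shape)
        return out.T.reshape(-1, H, W)

    def backward(self, dy):
        cols, xshape = self._cache
        k = self.k
        pad = k // 2
        c_in, H, W = xshape
        c_out = dy.shape[0]
        dyf = dy.reshape(c_out, H * W).T
        self.dW = (dyf.T @ cols).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.W.reshape(c_out, -1)).reshape(H, W, c_in, k, k)
        dxp = np.zeros((c_in, H + 2 * pad, W + 2 * pad))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W] += dcols[:, :, :, i, j].transpose(2, 0, 1)
        return dxp[:, pad:pad + H, pad:pad + W] if pad else dxp

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]

    def step(self, lr):
        self.W -= lr * self.dW
        self.b -= lr * self.db


class _InstanceNorm:
    """Per-channel normalisation over the spatial axes, with learnable
    scale/shift."""

    EPS = 1e-5

    def __init__(self, channels):
        self.g = np.ones(channels)
        self.beta = np.zeros(channels)
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.dg = (dy * xhat).sum(axis=(1, 2))
        self.dbeta = dy.sum(axis=(1, 2))
        dxhat = dy * self.g[:, None, None]
        return inv / n * (
            n * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        )

    def step(self, lr):
        self.g -= lr * self.dg
        self.beta -= lr * self.dbeta


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def step(self, lr):
        pass


class _ConvBlock:
    """conv -> instance norm -> relu, twice."""

    def __init__(self, rng, c_in, c_out):
        self.layers = [
            _Conv2D(rng, c_in, c_out), _InstanceNorm(c_out), _ReLU(),
            _Conv2D(rng, c_out, c_out), _InstanceNorm(c_out), _ReLU(),
        ]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def step(self, lr):
        for layer in self.layers:
            layer.step(lr)


def _maxpool2(x):
    c, H, W = x.shape
    xr = x.reshape(c, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None]
    # break ties: keep only the first max in each window
    flat = mask.reshape(c, H // 2, W // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(mask.shape)
    return out, mask


def _maxpool2_backward(dy, mask):
    return (dy[:, :, None, :, None] * mask).reshape(
        mask.shape[0], mask.shape[1] * 2, mask.shape[3] * 2)


def _upsample2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dy):
    c, H, W = dy.shape
    return dy.reshape(c, H // 2, 2, W // 2, 2).sum(axis=(2, 4))


class TinyUNet:
    """Two-level U-Net on single-channel images; logits out, class axis first."""

    def __init__(self, n_classes, base_filters=8, seed=0, in_channels=1):
        rng = np.random.default_rng(seed)
        F = base_filters
        self.enc = _ConvBlock(rng, in_channels, F)
        self.mid = _ConvBlock(rng, F, 2 * F)
        self.up = _Conv2D(rng, 2 * F, F)
        self.dec = _ConvBlock(rng, 2 * F, F)
        self.head = _Conv2D(rng, F, n_classes, k=1)
        self.n_classes = n_classes

    def forward(self, image):
        x = image[None] if image.ndim == 2 else image
        e = self.enc.forward(x)
        pooled, self._pool_mask = _maxpool2(e)
        m = self.mid.forward(pooled)
        u = self.up.forward(_upsample2(m))
        d = self.dec.forward(np.concatenate([u, e], axis=0))
        self._skip_channels = e.shape[0]
        return self.head.forward(d)

    def backward(self, dlogits):
        dd = self.head.backward(dlogits)
        dcat = self.dec.backward(dd)
        du, de_skip = dcat[:-self._skip_channels], dcat[-self._skip_channels:]
        dm = _upsample2_backward(self.up.backward(du))
        dpool = self.mid.backward(dm)
        de = _maxpool2_backward(dpool, self._pool_mask) + de_skip
        self.enc.backward(de)

    def step(self, lr):
        for part in (self.enc, self.mid, self.up, self.dec, self.head):
            part.step(lr)


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` when the monitored loss has not improved
    for ``patience`` consecutive epochs."""

    def __init__(self, factor=0.1, patience=25):
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def update(self, loss, lr):
        if loss < self.best:
            self.best = loss
            self.wait = 0
            return lr
        self.wait += 1
        if self.wait >= self.patience:
            self.wait = 0
            return lr * self.factor
        return lr


class EarlyStopping:
    """Signal a stop when the monitored loss has not improved for
    ``patience`` consecutive epochs."""

    def __init__(self, patience=50):
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def update(self, loss) -> bool:
        if loss < self.best:
            self.best = loss
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class TinyUNetSegmenter(BaseEstimator):
    """Sklearn-style segmentation estimator trained with any registered loss.

    Parameters
    ----------
    loss : str
        Registry name ("ce", "focal", "dsc", "dsc++", "tversky", ...).
    loss_config : LossConfig or None
        Hyperparameters; None uses the published defaults.
    base_filters, lr, max_epochs, lr_factor, lr_patience, stop_patience :
        Model width and SGD/callback settings (SGD, batch size 1, initial
        LR 0.1, plateau factor 0.1).
    val_fraction : float
        Fraction of the training set carved out for the validation loss when
        no explicit validation set is passed to :meth:`fit`.
    seed : int
        Seeds weight init and shuffling.

    Fitted attributes: ``net_``, ``n_classes_``, ``history_`` (per-epoch
    train/val loss and LR), ``n_epochs_``.
    """

    def __init__(self, loss="dsc++", loss_config=None, base_filters=8,
                 lr=0.1, max_epochs=100, lr_factor=0.1, lr_patience=25,
                 stop_patience=50, val_fraction=0.2, seed=0, verbose=0):
        self.loss = loss
        self.loss_config = loss_config
        self.base_filters = base_filters
        self.lr = lr
        self.max_epochs = max_epochs
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.verbose = verbose

    def _cfg(self) -> LossConfig:
        return self.loss_config if self.loss_config is not None else LossConfig()

    def fit(self, X, y, X_val=None, y_val=None):
        get_loss(self.loss)  # fail fast on unknown names
        X = [np.asarray(x, dtype=np.float64) for x in X]
        y = [np.asarray(m) for m in y]
        if len(X) != len(y):
            raise ParameterError(f"{len(X)} images vs {len(y)} masks")
        cfg = self._cfg()
        n_classes = int(max(int(m.max()) for m in y) + 1)
        n_classes = max(n_classes, 2)
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = [y[i] for i in val_idx]
            X, y = [X[i] for i in tr_idx], [y[i] for i in tr_idx]
        y_hot = [one_hot_encode(m, n_classes) for m in y]
        yv_hot = [one_hot_encode(m, n_classes) for m in y_val]

        net = TinyUNet(n_classes, self.base_filters, seed=self.seed)
        lr = self.lr
        plateau = ReduceLROnPlateau(self.lr_factor, self.lr_patience)
        stopper = EarlyStopping(self.stop_patience)
        history = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            train_losses = []
            for i in order:
                logits = net.forward(X[i])
                z = logits.transpose(1, 2, 0)  # class axis last for the loss
                value, dz = loss_gradient_logits(self.loss, z, y_hot[i], cfg)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite {self.loss} loss at epoch {epoch}, "
                        f"image {i}: {value}")
                net.backward(dz.transpose(2, 0, 1))
                net.step(lr)
                train_losses.append(value)
            val = float(np.mean([
                loss_value(self.loss, self._predict_one(net, xv), yv, cfg)
                for xv, yv in zip(X_val, yv_hot)]))
            history.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                            "val_loss": val, "lr": lr})
            if self.verbose:
                print(f"epoch {epoch}: train {np.mean(train_losses):.4f} "
                      f"val {val:.4f} lr {lr:g}")
            lr = plateau.update(val, lr)
            if stopper.update(val):
                break
        self.net_ = net
        self.n_classes_ = n_classes
        self.history_ = history
        self.n_epochs_ = len(history)
        return self

    @staticmethod
    def _predict_one(net, image):
        z = net.forward(np.asarray(image, dtype=np.float64)).transpose(1, 2, 0)
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_proba(self, X):
        """Per-pixel class probabilities, one (H, W, C) map per image."""
        return [self._predict_one(self.net_, x) for x in X]

    def predict(self, X):
        """Argmax label masks."""
        return [np.argmax(p, axis=-1) for p in self.predict_proba(X)]
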