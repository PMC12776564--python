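"""Scikit-learn style estimators for the two segmentation networks.

``SemiSiameseUNet`` is the shared-encoder / dual-decoder network with the
multi-weighted BCE objective; ``ClassicalUNet`` is the standard
one-decoder U-Net baseline with a two-channel head and (by default) unit
weights.  Both follow the sklearn estimator contract: hyperparameters in
``__init__``, ``fit(X, y)``, ``predict`` / ``predict_proba``, fitted
attributes with a trailing underscore, ``get_params`` / ``set_params``
inherited from :class:`sklearn.base.BaseEstimator`.

Inputs ``X`` are ``(n, H, W)`` images normalized to [0, 1]; targets ``y``
are ``(n, 2, H, W)`` with channel 0 the lung map and channel 1 the heart
map, values in [0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .losses import EPS_DEFAULT, LossWeights, bce, bce_grad_logits, sigmoid
from .metrics import dice, mae
from .nn.layers import Adam
from .nn.unet import (BaselineNet, SemiSiameseNet, get_weights,
                      parameter_count, set_training, set_weights)


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _validate_xy(X, y=None):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3:
        raise ValueError(f"X must be (n_samples, H, W), got shape {X.shape}")
    n, h, w = X.shape
    if y is None:
        return X
    y = np.asarray(y, dtype=np.float32)
    if y.shape != (n, 2, h, w):
        raise ValueError(
            f"y must be (n_samples, 2, H, W) = ({n}, 2, {h}, {w}), "
            f"got {y.shape}"
        )
    return X, y


class _BaseUNetEstimator(BaseEstimator):
    _n_heads = 2

    def __init__(self, base_channels=16, depth=4, w_lung=1.0, w_heart=1.0,
                 learning_rate=1e-3, lr_schedule="cosine", batch_size=32,
                 epochs=60, patience=10, clip_eps=EPS_DEFAULT, head_bias=-2.0,
                 augment_flip=True, random_state=0, verbose=0):
        self.base_channels = base_channels
        self.depth = depth
        self.w_lung = w_lung
        self.w_heart = w_heart
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.clip_eps = clip_eps
        self.head_bias = head_bias
        self.augment_flip = augment_flip
        self.random_state = random_state
        self.verbose = verbose

    # -- subclass hooks ----------------------------------------------------
    def _build_net(self, rng: np.random.Generator):
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def build(self):
        """Initialize the network without training (for inspection/inference)."""
        h = 2 ** (self.depth - 1)
        if 32 % h:
            raise ValueError(
                f"depth {self.depth} incompatible with 32x32 inputs"
            )
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(rng)
        self.n_parameters_ = parameter_count(self.net_)
        return self

    def fit(self, X, y, validation_data=None):
        """Train with Adam on the weighted two-task BCE.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair; when
        given, per-epoch validation loss and per-task Dice/MAE are logged
        and the weights with the best validation loss are retained
        (early stopping after ``patience`` epochs without improvement).
        """
        X, y = _validate_xy(X, y)
        weights = LossWeights(self.w_lung, self.w_heart)
        rng = np.random.default_rng(self.random_state)
        self.build()
        net = self.net_
        opt = Adam(net.parameters(), lr=self.learning_rate)

        has_val = validation_data is not None
        if has_val:
            Xv, yv = _validate_xy(*validation_data)

        history = {k: [] for k in
                   ("epoch", "train_loss", "val_loss",
                    "val_dice_lung", "val_dice_heart",
                    "val_mae_lung", "val_mae_heart")}
        best_loss, best_w, bad_epochs = np.inf, None, 0
        n = X.shape[0]
        bs = min(self.batch_size, n)

        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                # anneal to ~2% of the initial rate over the epoch budget
                opt.lr = self.learning_rate * (
                    0.02 + 0.98 * 0.5 * (1 + np.cos(np.pi * epoch / self.epochs))
                )
            order = rng.permutation(n)
            losses = []
            set_training(net, True)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb = X[idx][:, None]
                lung_t, heart_t = y[idx, :1], y[idx, 1:]
                if self.augment_flip:
                    # the phantom distribution is mirror-symmetric about the
                    # vertical axis, so left-right flips are label-exact
                    flip = rng.random(len(idx)) < 0.5
                    xb = xb.copy()
                    lung_t, heart_t = lung_t.copy(), heart_t.copy()
                    xb[flip] = xb[flip, :, :, ::-1]
                    lung_t[flip] = lung_t[flip, :, :, ::-1]
                    heart_t[flip] = heart_t[flip, :, :, ::-1]
                lung_logit, heart_logit = net.forward(xb)
                lung_p = sigmoid(lung_logit)
                heart_p = sigmoid(heart_logit)
                loss = (weights.w_lung * bce(lung_p, lung_t, self.clip_eps)
                        + weights.w_heart * bce(heart_p, heart_t,
                                                self.clip_eps))
                if not np.isfinite(loss):
                    raise TrainingDivergence(
                        f"non-finite loss {loss} at epoch {epoch}, "
                        f"batch start {start}"
                    )
                losses.append(loss)
                opt.zero_grad()
                net.backward(
                    weights.w_lung * bce_grad_logits(lung_p, lung_t),
                    weights.w_heart * bce_grad_logits(heart_p, heart_t),
                )
                opt.step()

            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(losses)))
            if has_val:
                lp, hp = self._forward_proba(Xv)
                vloss = (weights.w_lung * bce(lp, yv[:, 0], self.clip_eps)
                         + weights.w_heart * bce(hp, yv[:, 1],
                                                 self.clip_eps))
                history["val_loss"].append(float(vloss))
                history["val_dice_lung"].append(
                    float(np.mean([dice(l >= 0.5, t >= 0.5)
                                   for l, t in zip(lp, yv[:, 0])])))
                history["val_dice_heart"].append(
                    float(np.mean([dice(h >= 0.5, t >= 0.5)
                                   for h, t in zip(hp, yv[:, 1])])))
                history["val_mae_lung"].append(
                    float(np.mean([mae(l, t) for l, t in zip(lp, yv[:, 0])])))
                history["val_mae_heart"].append(
                    float(np.mean([mae(h, t) for h, t in zip(hp, yv[:, 1])])))
                if vloss < best_loss - 1e-12:
                    best_loss, best_w, bad_epochs = vloss, get_weights(net), 0
                else:
                    bad_epochs += 1
                if self.verbose:
                    print(f"epoch {epoch:3d}  train {history['train_loss'][-1]:.5f}"
                          f"  val {vloss:.5f}  heart dice "
                          f"{history['val_dice_heart'][-1]:.4f}")
                if bad_epochs > self.patience:
                    break
            else:
                for k in list(history):
                    if k.startswith("val"):
                        history[k].append(np.nan)

        set_training(net, False)
        if best_w is not None:
            set_weights(net, best_w)
        self.history_ = history
        self.best_val_loss_ = best_loss if has_val else None
        self.n_epochs_run_ = len(history["epoch"])
        return self

    def _forward_proba(self, X, batch: int = 64):
        set_training(self.net_, False)
        lungs, hearts = [], []
        for start in range(0, X.shape[0], batch):
            ll, hl = self.net_.forward(X[start:start + batch][:, None])
            lungs.append(sigmoid(ll)[:, 0])
            hearts.append(sigmoid(hl)[:, 0])
        return np.concatenate(lungs), np.concatenate(hearts)

    def predict_proba(self, X):
        """Per-pixel probability maps, shape ``(n, 2, H, W)`` (lung, heart)."""
        check_is_fitted(self, "net_")
        X = _validate_xy(X)
        lp, hp = self._forward_proba(X)
        return np.stack([lp, hp], axis=1)

    def predict(self, X, threshold: float = 0.5):
        """Binarized masks at the given threshold, shape ``(n, 2, H, W)``."""
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def score(self, X, y):
        """Mean heart Dice on binarized predictions (higher is better)."""
        X, y = _validate_xy(X, y)
        pred = self.predict(X)
        return float(np.mean(
            [dice(p, t >= 0.5) for p, t in zip(pred[:, 1], y[:, 1])]
        ))


class SemiSiameseUNet(_BaseUNetEstimator):
    """Shared-encoder, dual-decoder U-Net for lung/heart signal separation.

    Parameters mirror the classical U-Net recipe scaled to 32x32 inputs:
    ``depth`` resolution levels (default 4: 32-16-8-4), ``base_channels``
    at the first level doubling per level, double 3x3 conv blocks, 2x2
    max-pooling down and nearest-upsample + conv up, skip concatenation
    into both decoders.  ``w_lung`` / ``w_heart`` are the task weights of
    the multi-weighted BCE; their ratio is the tuning constant Wc.
    """

    def _build_net(self, rng):
        return SemiSiameseNet(self.base_channels, self.depth, rng,
                              head_bias=self.head_bias)

    @property
    def wc(self) -> float:
        return LossWeights(self.w_lung, self.w_heart).wc


class ClassicalUNet(_BaseUNetEstimator):
    """Single-decoder U-Net baseline with a 2-channel sigmoid head."""

    def _build_net(self, rng):
        return BaselineNet(self.base_channels, self.depth, rng,
                           head_bias=self.head_bias)
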