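"""A compact sequential CNN for 100x100 grayscale mammograms, in numpy.

The network is the classical small stack: convolution (valid, 3x3) + ReLU +
2x2 max-pooling blocks, one dense ReLU layer with dropout, and a single
sigmoid output giving the malignancy probability.  Training uses mini-batch
Adam on a class-weighted binary cross-entropy; with the default 271-vs-51
class imbalance an unweighted loss would reward the degenerate all-negative
classifier (84% accuracy), so classes are reweighted inversely to their
frequency.

Everything — weight initialisation, the 25% validation split, batch
shuffling and dropout masks — is driven by explicit seeds, so a fixed seed
reproduces weights, splits and scores bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "TrainedModel", "DegenerateDataError",
           "build_model", "train", "predict_proba", "validation_size"]


class DegenerateDataError(ValueError):
    """Raised when the training partition contains a single class."""


@dataclass
class ModelConfig:
    input_size: Tuple[int, int] = (100, 100)
    #: (filters, kernel, pool) per block
    conv_blocks: Tuple[Tuple[int, int, int], ...] = ((16, 3, 2), (32, 3, 2),
                                                     (64, 3, 2))
    dense_units: int = 64
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    class_weighting: bool = True

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        h, w = self.input_size
        for f, k, p in self.conv_blocks:
            h, w = (h - k + 1) // p, (w - k + 1) // p
            if h < 1 or w < 1:
                raise ValueError("conv/pool stack consumes the whole image")

    def feature_shape(self) -> Tuple[int, int, int]:
        """(channels, height, width) entering the dense layer."""
        h, w = self.input_size
        ch = 1
        for f, k, p in self.conv_blocks:
            h, w = (h - k + 1) // p, (w - k + 1) // p
            ch = f
        return ch, h, w

    def param_count(self) -> int:
        """Analytic number of trainable parameters."""
        n, cin = 0, 1
        for f, k, _ in self.conv_blocks:
            n += f * cin * k * k + f
            cin = f
        ch, h, w = self.feature_shape()
        n += ch * h * w * self.dense_units + self.dense_units
        n += self.dense_units + 1
        return n


# ---------------------------------------------------------------------------
# layer primitives (forward + backward), operating on (N, C, H, W) tensors


def _conv_forward(x, w, b):
    win = sliding_window_view(x, (w.shape[2], w.shape[3]), axis=(2, 3))
    out = np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)
    out += b[None, :, None, None]
    return out, win


def _conv_backward(dout, win, w, x_shape):
    dw = np.einsum("nfhw,nchwij->fcij", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    k = w.shape[2]
    pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    pwin = sliding_window_view(pad, (k, k), axis=(2, 3))
    dx = np.einsum("nfhwij,fcij->nchw", pwin, w[:, :, ::-1, ::-1],
                   optimize=True)
    return dx, dw, db


def _pool_forward(x, p):
    n, c, h, w = x.shape
    hp, wp = h // p, w // p
    xc = x[:, :, : hp * p, : wp * p]
    resh = xc.reshape(n, c, hp, p, wp, p).transpose(0, 1, 2, 4, 3, 5)
    flat = resh.reshape(n, c, hp, wp, p * p)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, p)


def _pool_backward(dout, cache):
    idx, x_shape, p = cache
    n, c, h, w = x_shape
    hp, wp = h // p, w // p
    flat = np.zeros((n, c, hp, wp, p * p), dtype=dout.dtype)
    np.put_along_axis(flat, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : hp * p, : wp * p] = (
        flat.reshape(n, c, hp, wp, p, p).transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, hp * p, wp * p))
    return dx


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
                    np.exp(np.clip(z, -500, 500))
                    / (1.0 + np.exp(np.clip(z, -500, 500))))


class CNN:
    """The network object: parameters plus forward/backward passes."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        cin = 1
        for i, (f, k, _) in enumerate(config.conv_blocks):
            fan_in = cin * k * k
            self.params[f"Wc{i}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), (f, cin, k, k)).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            cin = f
        ch, h, w = config.feature_shape()
        d = config.dense_units
        self.params["W1"] = rng.normal(
            0, np.sqrt(2.0 / (ch * h * w)), (ch * h * w, d)).astype(np.float32)
        self.params["b1"] = np.zeros(d, dtype=np.float32)
        self.params["W2"] = rng.normal(
            0, np.sqrt(1.0 / d), (d, 1)).astype(np.float32)
        self.params["b2"] = np.zeros(1, dtype=np.float32)
        # Adam state
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != tuple(self.config.input_size):
            raise ValueError(f"expected images of shape "
                             f"{self.config.input_size}, got {x.shape[1:]}")
        if x.max() > 1.0:
            x = x / 255.0
        return x[:, None]  # add channel axis

    def forward(self, x, dropout_rng=None):
        cache = {"acts": []}
        a = x
        for i, (_, _, p) in enumerate(self.config.conv_blocks):
            z, win = _conv_forward(a, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            mask = z > 0
            a_out, pool_cache = _pool_forward(z * mask, p)
            cache["acts"].append((win, mask, pool_cache, a.shape))
            a = a_out
        n = a.shape[0]
        flat = a.reshape(n, -1)
        z1 = flat @ self.params["W1"] + self.params["b1"]
        m1 = z1 > 0
        h1 = z1 * m1
        if dropout_rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dmask = (dropout_rng.random(h1.shape) < keep) / keep
            h1 = h1 * dmask
        else:
            dmask = None
        z2 = h1 @ self.params["W2"] + self.params["b2"]
        prob = _sigmoid(z2)[:, 0]
        cache.update(flat=flat, m1=m1, h1=h1, dmask=dmask, conv_out_shape=a.shape)
        return prob, cache

    def backward(self, prob, y, sample_w, cache):
        n = len(y)
        grads = {}
        dz2 = (sample_w * (prob - y) / n)[:, None].astype(np.float32)
        grads["W2"] = cache["h1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ self.params["W2"].T
        if cache["dmask"] is not None:
            dh1 = dh1 * cache["dmask"]
        dz1 = dh1 * cache["m1"]
        grads["W1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        da = (dz1 @ self.params["W1"].T).reshape(cache["conv_out_shape"])
        for i in range(len(self.config.conv_blocks) - 1, -1, -1):
            win, mask, pool_cache, in_shape = cache["acts"][i]
            dz = _pool_backward(da, pool_cache) * mask
            da, dw, db = _conv_backward(dz, win, self.params[f"Wc{i}"], in_shape)
            grads[f"Wc{i}"] = dw
            grads[f"bc{i}"] = db
        return grads

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        for k, g in grads.items():
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * g
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * g * g
            mhat = self._m[k] / (1 - beta1 ** self._t)
            vhat = self._v[k] / (1 - beta2 ** self._t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(
                self.params[k].dtype)

    def predict_proba(self, images) -> np.ndarray:
        x = self._check_input(images)
        out = []
        for i in range(0, len(x), 256):
            prob, _ = self.forward(x[i:i + 256])
            out.append(prob)
        return np.concatenate(out)


@dataclass
class TrainedModel:
    """Fitted network with its per-epoch history and configuration."""

    network: CNN
    history: List[dict]
    config: ModelConfig
    val_indices: np.ndarray | None = None

    def predict_proba(self, images) -> np.ndarray:
        return self.network.predict_proba(images)


def build_model(config: ModelConfig | None = None) -> CNN:
    """Construct the untrained network (seeded initial weights)."""
    return CNN(config or ModelConfig())


def validation_size(n: int, val_fraction: float = 0.25) -> int:
    """Number of validation images: round(val_fraction*n), half to even."""
    return int(round(val_fraction * n))


def _bce(prob, y, sample_w):
    p = np.clip(prob, 1e-7, 1 - 1e-7)
    return float(-np.mean(sample_w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def train(model: CNN, images: Sequence[np.ndarray], labels: Sequence[int],
          val_fraction: float = 0.25, seed: int = 0) -> TrainedModel:
    """Fit the network with a seeded validation split and mini-batch Adam.

    ``round(val_fraction * n)`` images (banker's rounding) are held out for
    validation; the rest are trained on with class-weighted BCE.
    """
    cfg = model.config
    x = model._check_input(np.stack([np.asarray(im) for im in images]))
    y = np.asarray(labels, dtype=np.float32)
    if len(x) != len(y):
        raise ValueError("images and labels length mismatch")
    if np.unique(y).size < 2:
        raise DegenerateDataError("training data contains a single class")
    rng = np.random.default_rng(seed)
    n = len(y)
    n_val = validation_size(n, val_fraction)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[tr_idx]).size < 2:
        raise DegenerateDataError("training partition lost a class in the split")

    if cfg.class_weighting:
        counts = np.array([(y[tr_idx] == 0).sum(), (y[tr_idx] == 1).sum()],
                          dtype=float)
        cw = len(tr_idx) / (2.0 * counts)
    else:
        cw = np.ones(2)
    w_all = cw[y.astype(int)].astype(np.float32)

    drop_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
    history: List[dict] = []
    for _ in range(cfg.epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        losses, accs, sizes = [], [], []
        for s in range(0, len(order), cfg.batch_size):
            b = order[s:s + cfg.batch_size]
            prob, cache = model.forward(x[b], dropout_rng=drop_rng)
            grads = model.backward(prob, y[b], w_all[b], cache)
            model.adam_step(grads, cfg.learning_rate)
            losses.append(_bce(prob, y[b], w_all[b]))
            accs.append(float(((prob >= 0.5) == y[b]).mean()))
            sizes.append(len(b))
        sizes = np.array(sizes, dtype=float)
        rec = {"loss": float(np.average(losses, weights=sizes)),
               "accuracy": float(np.average(accs, weights=sizes))}
        if n_val:
            vp = model.predict_proba(x[val_idx, 0])
            rec["val_loss"] = _bce(vp, y[val_idx], w_all[val_idx])
            rec["val_accuracy"] = float(((vp >= 0.5) == y[val_idx]).mean())
        history.append(rec)
    return TrainedModel(network=model, history=history, config=cfg,
                        val_indices=val_idx)


def predict_proba(trained: TrainedModel | CNN, images) -> np.ndarray:
    """Malignancy scores in [0, 1], one per image."""
    return trained.predict_proba(images)
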