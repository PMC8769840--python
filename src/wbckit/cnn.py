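"""Small convolutional feature extractor with pure-array backprop.

The network is deliberately minimal: one valid (unpadded) 3x3
convolution layer with ReLU, two 2x2 max-pooling layers, and two fully
connected layers.  The penultimate fully connected activations serve as
the learned feature vector handed to the sparse-representation
classifier; the final softmax layer exists only to train the network by
cross-entropy backpropagation.

Everything is float64 numpy: parameters live in a plain dict of named
arrays, gradients are hand-derived and validated against central finite
differences, and all randomness (initialization, shuffling) flows from
a single seed, so training is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CNNConfig",
    "conv_valid",
    "max_pool",
    "init_params",
    "forward",
    "loss_and_grads",
    "cross_entropy",
    "train",
    "save_params",
    "load_params",
]


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters.

    input spatial size and channel count describe the nucleus crops the
    network consumes; n_filters and hidden_width size the conv layer
    and the penultimate (feature) layer.  Plain SGD with a fixed
    learning rate keeps optimization transparent and reproducible.
    """

    input_size: int = 64
    in_channels: int = 3
    n_filters: int = 16
    hidden_width: int = 128
    n_classes: int = 5
    pool_window: int = 2
    pool_stride: int = 2
    lr: float = 0.01
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0

    @property
    def flat_width(self) -> int:
        s = self.input_size - 2  # valid 3x3 conv
        for _ in range(2):
            s = (s - self.pool_window) // self.pool_stride + 1
        if s < 1:
            raise ValueError("input too small for conv + two pooling layers")
        return self.n_filters * s * s


def conv_valid(x, filters, biases=None):
    """Valid 3x3 cross-correlation; output shrinks by 2 per spatial axis.

    Parameters
    ----------
    x : (C, H, W) or (B, C, H, W) array
    filters : (K, C, 3, 3) array
    biases : (K,) array, optional

    Notes
    -----
    Implemented as cross-correlation (no kernel flip); since the
    filters are learned the distinction is immaterial.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    filters = np.asarray(filters, dtype=float)
    if filters.shape[-2:] != (3, 3):
        raise ValueError("filters must be 3x3")
    if x.shape[2] < 3 or x.shape[3] < 3:
        raise ValueError("input spatial dims must be >= 3")
    windows = sliding_window_view(x, (3, 3), axis=(2, 3))
    z = np.einsum("bchwij,kcij->bkhw", windows, filters)
    if biases is not None:
        z += np.asarray(biases, dtype=float)[None, :, None, None]
    return z[0] if single else z


def max_pool(fm, window: int = 2, stride: int = 2):
    """Max pooling over window x window neighborhoods."""
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    fm = np.asarray(fm, dtype=float)
    single = fm.ndim == 3
    if single:
        fm = fm[None]
    wins = sliding_window_view(fm, (window, window), axis=(2, 3))
    wins = wins[:, :, ::stride, ::stride]
    out = wins.max(axis=(-2, -1))
    return out[0] if single else out


def _pool_forward(fm, window, stride):
    """Pooling with the argmax bookkeeping needed for backprop."""
    wins = sliding_window_view(fm, (window, window), axis=(2, 3))
    wins = wins[:, :, ::stride, ::stride]
    b, c, oh, ow = wins.shape[:4]
    flat = wins.reshape(b, c, oh, ow, window * window)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _pool_backward(dout, arg, in_shape, window, stride):
    b, c, oh, ow = dout.shape
    dx = np.zeros(in_shape)
    wi, wj = np.unravel_index(arg, (window, window))
    oi = np.arange(oh)[None, None, :, None] * stride + wi
    oj = np.arange(ow)[None, None, None, :] * stride + wj
    bi = np.arange(b)[:, None, None, None]
    ci = np.arange(c)[None, :, None, None]
    np.add.at(dx, (bi, ci, oi, oj), dout)
    return dx


def init_params(cfg: CNNConfig, seed: int | None = None) -> dict:
    """He-initialized parameter dict for the configured architecture."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k, c = cfg.n_filters, cfg.in_channels
    flat = cfg.flat_width
    return {
        "conv_w": rng.normal(0, np.sqrt(2.0 / (c * 9)), size=(k, c, 3, 3)),
        "conv_b": np.zeros(k),
        "fc1_w": rng.normal(0, np.sqrt(2.0 / flat), size=(cfg.hidden_width, flat)),
        "fc1_b": np.zeros(cfg.hidden_width),
        "fc2_w": rng.normal(
            0, np.sqrt(2.0 / cfg.hidden_width), size=(cfg.n_classes, cfg.hidden_width)
        ),
        "fc2_b": np.zeros(cfg.n_classes),
    }


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, onehot) -> float:
    """Mean cross-entropy; zero exactly when predictions match labels."""
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    eps = np.finfo(float).tiny
    return float(-np.sum(onehot * np.log(probs + eps)) / probs.shape[0])


def forward(x, params: dict, cfg: CNNConfig, mode: str = "probs"):
    """Run the network on a batch (or single) input.

    mode="probs" returns class probabilities, "logits" the raw scores,
    "features" the penultimate fully connected activations used as the
    learned feature vector.
    """
    out, _ = _forward_cached(np.asarray(x, dtype=float), params, cfg, mode)
    return out


def _forward_cached(x, params, cfg, mode="probs"):
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.shape[1:] != (cfg.in_channels, cfg.input_size, cfg.input_size):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match conv layer "
            f"({cfg.in_channels}, {cfg.input_size}, {cfg.input_size})"
        )
    cache: dict = {"x": x}
    z = conv_valid(x, params["conv_w"], params["conv_b"])
    cache["conv_pre"] = z
    a = np.maximum(z, 0.0)
    cache["conv_act"] = a
    p1, arg1 = _pool_forward(a, cfg.pool_window, cfg.pool_stride)
    cache["p1"], cache["arg1"] = p1, arg1
    p2, arg2 = _pool_forward(p1, cfg.pool_window, cfg.pool_stride)
    cache["p2"], cache["arg2"] = p2, arg2
    flat = p2.reshape(p2.shape[0], -1)
    cache["flat"] = flat
    h_pre = flat @ params["fc1_w"].T + params["fc1_b"]
    cache["h_pre"] = h_pre
    h = np.maximum(h_pre, 0.0)
    cache["h"] = h
    if mode == "features":
        return (h[0] if single else h), cache
    logits = h @ params["fc2_w"].T + params["fc2_b"]
    cache["logits"] = logits
    if mode == "logits":
        return (logits[0] if single else logits), cache
    probs = _softmax(logits)
    cache["probs"] = probs
    return (probs[0] if single else probs), cache


def loss_and_grads(x, onehot, params: dict, cfg: CNNConfig):
    """Mean cross-entropy over the batch and gradients for every tensor."""
    x = np.asarray(x, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    probs, cache = _forward_cached(x, params, cfg, mode="probs")
    n = x.shape[0]
    loss = cross_entropy(probs, onehot)

    dlogits = (probs - onehot) / n
    grads = {
        "fc2_w": dlogits.T @ cache["h"],
        "fc2_b": dlogits.sum(axis=0),
    }
    dh = dlogits @ params["fc2_w"]
    dh_pre = dh * (cache["h_pre"] > 0)
    grads["fc1_w"] = dh_pre.T @ cache["flat"]
    grads["fc1_b"] = dh_pre.sum(axis=0)
    dflat = dh_pre @ params["fc1_w"]
    dp2 = dflat.reshape(cache["p2"].shape)
    dp1 = _pool_backward(
        dp2, cache["arg2"], cache["p1"].shape, cfg.pool_window, cfg.pool_stride
    )
    da = _pool_backward(
        dp1, cache["arg1"], cache["conv_act"].shape, cfg.pool_window, cfg.pool_stride
    )
    dz = da * (cache["conv_pre"] > 0)
    windows = sliding_window_view(cache["x"], (3, 3), axis=(2, 3))
    grads["conv_w"] = np.einsum("bchwij,bkhw->kcij", windows, dz)
    grads["conv_b"] = dz.sum(axis=(0, 2, 3))
    # input gradient not needed for training, only parameter gradients
    return loss, grads


def _to_onehot(labels, n_classes):
    labels = np.asarray(labels, dtype=int)
    oh = np.zeros((labels.shape[0], n_classes))
    oh[np.arange(labels.shape[0]), labels] = 1.0
    return oh


def train(X, labels, cfg: CNNConfig):
    """Minibatch SGD on cross-entropy; returns (params, loss_history).

    ``X`` is (N, C, H, W); ``labels`` integer class ids.  Deterministic
    given ``cfg.seed`` (initialization and shuffling share the seed).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes")
    onehot = _to_onehot(labels, cfg.n_classes)
    params = init_params(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = loss_and_grads(X[idx], onehot[idx], params, cfg)
            for name, g in grads.items():
                params[name] -= cfg.lr * g
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return params, history


def save_params(path, params: dict) -> None:
    """Persist parameters as a single archive of named arrays."""
    np.savez(path, **params)


def load_params(path) -> dict:
    with np.load(path) as data:
        return {name: data[name].copy() for name in data.files}
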