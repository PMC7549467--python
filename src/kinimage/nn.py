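"""Compact numpy implementation of the activity-image CNN.

The network is small (two 3x3 valid convolutions with max-pooling, one
hidden dense layer with dropout, softmax output) and the images are tiny
(12 x 32 x C), so a vectorized numpy implementation trains in seconds and
is bit-reproducible given a seed — every source of randomness (weight
initialization, batch shuffling, dropout masks) is drawn from one
``numpy.random.Generator``.

Convolutions are computed with ``sliding_window_view`` patches and
``einsum``; the backward pass accumulates the nine kernel-offset
contributions explicitly.  Max-pooling uses a first-occurrence argmax so
tie-breaking is deterministic.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import BuildError

KERNEL = 3
POOL = 2


def conv_output_shape(h: int, w: int) -> Tuple[int, int]:
    return h - KERNEL + 1, w - KERNEL + 1


def pool_output_shape(h: int, w: int) -> Tuple[int, int]:
    return h // POOL, w // POOL


def spatial_trace(h: int, w: int) -> List[Tuple[int, int]]:
    """Spatial sizes after conv1, pool1, conv2, pool2 for an (h, w) input."""
    shapes = []
    h, w = conv_output_shape(h, w)
    shapes.append((h, w))
    h, w = pool_output_shape(h, w)
    shapes.append((h, w))
    h, w = conv_output_shape(h, w)
    shapes.append((h, w))
    h, w = pool_output_shape(h, w)
    shapes.append((h, w))
    return shapes


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    patches = sliding_window_view(x, (KERNEL, KERNEL), axis=(1, 2))
    out = np.einsum("bhwcij,ijcf->bhwf", patches, w, optimize=True) + b
    return out, patches


def _conv_backward(dout: np.ndarray, patches: np.ndarray, w: np.ndarray, x_shape):
    dw = np.einsum("bhwcij,bhwf->ijcf", patches, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    dx = np.zeros(x_shape)
    ho, wo = dout.shape[1], dout.shape[2]
    for i in range(KERNEL):
        for j in range(KERNEL):
            dx[:, i : i + ho, j : j + wo, :] += np.einsum(
                "bhwf,cf->bhwc", dout, w[i, j], optimize=True
            )
    return dx, dw, db


def _pool_forward(x: np.ndarray):
    b, h, w, f = x.shape
    hp, wp = h // POOL, w // POOL
    cropped = x[:, : hp * POOL, : wp * POOL, :]
    windows = (
        cropped.reshape(b, hp, POOL, wp, POOL, f)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(b, hp, wp, f, POOL * POOL)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    b, h, w, f = x_shape
    hp, wp = h // POOL, w // POOL
    dwindows = np.zeros((b, hp, wp, f, POOL * POOL))
    np.put_along_axis(dwindows, idx[..., None], dout[..., None], axis=-1)
    dcropped = (
        dwindows.reshape(b, hp, wp, f, POOL, POOL)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, hp * POOL, wp * POOL, f)
    )
    dx = np.zeros(x_shape)
    dx[:, : hp * POOL, : wp * POOL, :] = dcropped
    return dx


class SmallCNN:
    """conv(f1) -> pool -> conv(f2) -> pool -> flatten -> dense -> dropout
    -> softmax, with ReLU activations on hidden layers."""

    def __init__(
        self,
        input_shape: Tuple[int, int, int],
        n_classes: int,
        f_conv1: int,
        f_conv2: int,
        out_dense1: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        h, w, c = input_shape
        trace = spatial_trace(h, w)
        if any(s < 1 for shape in trace for s in shape):
            raise BuildError(
                f"input {h}x{w} collapses under two valid 3x3 convs + 2x2 pools: {trace}"
            )
        self.input_shape = input_shape
        self.n_classes = int(n_classes)
        self.dropout = float(dropout)
        hp, wp = trace[-1]
        self.flat_size = hp * wp * f_conv2

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params: Dict[str, np.ndarray] = {
            "w1": he((KERNEL, KERNEL, c, f_conv1), KERNEL * KERNEL * c),
            "b1": np.zeros(f_conv1),
            "w2": he((KERNEL, KERNEL, f_conv1, f_conv2), KERNEL * KERNEL * f_conv1),
            "b2": np.zeros(f_conv2),
            "w3": he((self.flat_size, out_dense1), self.flat_size),
            "b3": np.zeros(out_dense1),
            "w4": he((out_dense1, n_classes), out_dense1),
            "b4": np.zeros(n_classes),
        }
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Return class probabilities (B, n_classes); caches intermediates
        for :meth:`backward` when ``train`` is True."""
        p = self.params
        z1, patches1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, pool1_cache = _pool_forward(a1)
        z2, patches2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, pool2_cache = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        if train and self.dropout > 0.0:
            if rng is None:
                raise ValueError("training forward pass with dropout needs an rng")
            mask = (rng.random(a3.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = None
        d3 = a3 * mask if mask is not None else a3
        logits = d3 @ p["w4"] + p["b4"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        if train:
            self._cache = {
                "x": x, "z1": z1, "patches1": patches1, "a1": a1,
                "pool1_cache": pool1_cache, "p1": p1, "z2": z2, "patches2": patches2,
                "a2": a2, "pool2_cache": pool2_cache, "p2": p2, "flat": flat,
                "z3": z3, "d3": d3, "mask": mask, "probs": probs,
            }
        return probs

    def backward(self, y_onehot: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of the mean cross-entropy w.r.t. every parameter."""
        c = self._cache
        if c is None:
            raise RuntimeError("call forward(train=True) before backward()")
        p = self.params
        batch = y_onehot.shape[0]
        grads: Dict[str, np.ndarray] = {}

        dlogits = (c["probs"] - y_onehot) / batch
        grads["w4"] = c["d3"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dd3 = dlogits @ p["w4"].T
        if c["mask"] is not None:
            dd3 = dd3 * c["mask"]
        dz3 = dd3 * (c["z3"] > 0)
        grads["w3"] = c["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dp2 = dflat.reshape(c["p2"].shape)
        da2 = _pool_backward(dp2, c["pool2_cache"])
        dz2 = da2 * (c["z2"] > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(dz2, c["patches2"], p["w2"], c["p1"].shape)
        da1 = _pool_backward(dp1, c["pool1_cache"])
        dz1 = da1 * (c["z1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(dz1, c["patches1"], p["w1"], c["x"].shape)
        self._cache = None
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            self.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(y_onehot * np.log(np.clip(probs, 1e-12, None)), axis=1)))
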