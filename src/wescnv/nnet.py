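"""Minimal NumPy neural-network primitives used by the classifier.

Only what the architecture needs: dense layers, strided same-padding 1-D
convolution via im2col, ReLU, inverted dropout, feature-axis softmax
attention, softmax cross-entropy, and Adam. All math is float32; forward
passes cache what the backward pass needs.

Same-padding here follows the ceiling convention: a convolution with stride
``s`` over length ``L`` yields ``ceil(L / s)`` positions, padding with zeros
(``pad_left = total_pad // 2``).
"""

from __future__ import annotations

import math

import numpy as np

F32 = np.float32


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def conv_output_length(length: int, stride: int) -> int:
    return math.ceil(length / stride)


def same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = conv_output_length(length, stride)
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(F32)


def glorot_init(rng, shape, fan_in, fan_out):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Dense:
    """Affine layer y = x W + b with optional ReLU."""

    def __init__(self, rng, n_in: int, n_out: int, activation: str = "relu"):
        if activation == "relu":
            self.W = he_init(rng, (n_in, n_out), n_in)
        else:
            self.W = glorot_init(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=F32)
        self.activation = activation

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        z = x @ self.W + self.b
        a = relu(z) if self.activation == "relu" else z
        if cache is not None:
            cache["x"], cache["z"] = x, z
        return a

    def backward(self, d_a: np.ndarray, cache: dict) -> np.ndarray:
        dz = d_a * (cache["z"] > 0) if self.activation == "relu" else d_a
        x = cache["x"]
        self.dW = (x.reshape(-1, x.shape[-1]).T @ dz.reshape(-1, dz.shape[-1]))
        self.db = dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class Conv1D:
    """Strided same-padding 1-D convolution with ReLU, via im2col."""

    def __init__(self, rng, n_in: int, n_filters: int, kernel: int, stride: int):
        self.kernel, self.stride, self.n_in = kernel, stride, n_in
        self.W = he_init(rng, (kernel * n_in, n_filters), kernel * n_in)
        self.b = np.zeros(n_filters, dtype=F32)

    def _geometry(self, length: int):
        out_len = conv_output_length(length, self.stride)
        pad_l, pad_r = same_padding(length, self.kernel, self.stride)
        starts = np.arange(out_len) * self.stride  # into the padded sequence
        return out_len, pad_l, pad_r, starts

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        B, L, C = x.shape
        out_len, pad_l, pad_r, starts = self._geometry(L)
        xp = np.zeros((B, L + pad_l + pad_r, C), dtype=F32)
        xp[:, pad_l:pad_l + L] = x
        # im2col via per-tap strided slices (taps are memory-contiguous)
        col = np.empty((B, out_len, self.kernel * C), dtype=F32)
        stop = (out_len - 1) * self.stride + 1
        for j in range(self.kernel):
            col[:, :, j * C:(j + 1) * C] = xp[:, j:j + stop:self.stride, :]
        z = col @ self.W + self.b
        a = relu(z)
        if cache is not None:
            cache.update(col=col, z=z, geom=(L, pad_l, pad_r, starts))
        return a

    def backward(self, d_a: np.ndarray, cache: dict,
                 need_input_grad: bool = True) -> np.ndarray | None:
        L, pad_l, pad_r, starts = cache["geom"]
        col, z = cache["col"], cache["z"]
        dz = d_a * (z > 0)
        B, out_len, F = dz.shape
        kC = self.kernel * self.n_in
        self.dW = col.reshape(-1, kC).T @ dz.reshape(-1, F)
        self.db = dz.reshape(-1, F).sum(axis=0)
        dcol = (dz @ self.W.T).reshape(B, out_len, self.kernel, self.n_in)
        if not need_input_grad:
            cache["dcol"] = dcol
            return None
        dxp = np.zeros((B, L + pad_l + pad_r, self.n_in), dtype=F32)
        # per-tap scatter; within one tap the strided positions are distinct
        stop = (out_len - 1) * self.stride + 1
        for j in range(self.kernel):
            dxp[:, j:j + stop:self.stride, :] += dcol[:, :, j, :]
        return dxp[:, pad_l:pad_l + L, :]

    def input_grad_channel_sum(self, cache: dict, from_channel: int) -> np.ndarray:
        """Position-summed input gradient for channels >= from_channel.

        Equivalent to ``backward(...)[:, :, from_channel:].sum(axis=1)`` but
        skips the full scatter; used for gradients of position-broadcast
        inputs (the repeated chromosome embedding).
        """
        L, pad_l, pad_r, starts = cache["geom"]
        dcol = cache["dcol"]
        s = dcol[:, :, :, from_channel:].sum(axis=(1, 2))
        for j in range(self.kernel):
            pos = starts + j
            bad = np.flatnonzero((pos < pad_l) | (pos >= pad_l + L))
            if bad.size:
                s -= dcol[:, bad, j, from_channel:].sum(axis=1)
        return s

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, *, rng: np.random.Generator | None, cache: dict | None = None):
        if rng is None or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        m = (rng.random(x.shape) < keep).astype(F32) / keep
        if cache is not None:
            cache["m"] = m
        return x * m

    def backward(self, d, cache: dict):
        return d * cache["m"] if "m" in cache else d


class FeatureAttention:
    """Softmax attention over the feature axis of a latent vector.

    Weights w = softmax(latent W + b) over the feature coordinates; the
    output is the elementwise product w * latent, so the layer reweights
    features by their relative importance while preserving dimensionality.
    """

    def __init__(self, rng, n_units: int):
        self.W = glorot_init(rng, (n_units, n_units), n_units, n_units)
        self.b = np.zeros(n_units, dtype=F32)

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        w = softmax(x @ self.W + self.b, axis=1)
        if cache is not None:
            cache["x"], cache["w"] = x, w
        return w * x

    def backward(self, d_out: np.ndarray, cache: dict) -> np.ndarray:
        x, w = cache["x"], cache["w"]
        dw = d_out * x
        ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))  # softmax jacobian
        self.dW = x.T @ ds
        self.db = ds.sum(axis=0)
        return d_out * w + ds @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy on integer labels; returns (loss, probs, dlogits)."""
    p = softmax(logits.astype(np.float64), axis=1)
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-15)).mean())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, p, (d / n).astype(F32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
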