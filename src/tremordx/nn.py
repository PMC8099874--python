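"""Minimal numpy CNN engine for the first-stage classifier.

Implements exactly the pieces the pipeline needs -- strided valid
convolution, max pooling, dense layers, ReLU / leaky ReLU, softmax
cross-entropy and Adam -- with explicit forward caches so gradients can be
taken both for training and for class-activation saliency maps.

Everything is deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvSpec",
    "NetworkShapes",
    "conv2d_forward",
    "conv2d_backward",
    "maxpool_forward",
    "maxpool_backward",
    "softmax",
    "softmax_cross_entropy",
    "Network",
    "Adam",
]


@dataclass(frozen=True)
class ConvSpec:
    filters: int
    kernel: int
    stride: int = 1
    pool: int = 2


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int):
    """Valid 2-D convolution (cross-correlation). x (N,C,H,W), w (F,C,kh,kw)."""
    kh, kw = w.shape[2], w.shape[3]
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # windows: (N, C, Ho, Wo, kh, kw)
    y = np.tensordot(windows, w, axes=([1, 4, 5], [1, 2, 3]))  # (N, Ho, Wo, F)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + b[None, :, None, None]
    return y, windows


def conv2d_backward(
    x_shape: tuple,
    windows: np.ndarray,
    w: np.ndarray,
    stride: int,
    dy: np.ndarray,
    need_dx: bool = True,
):
    """Gradients of conv2d_forward. dy (N,F,Ho,Wo)."""
    dw = np.tensordot(dy, windows, axes=([0, 2, 3], [0, 2, 3]))  # (F, C, kh, kw)
    db = dy.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        n, f, ho, wo = dy.shape
        kh, kw = w.shape[2], w.shape[3]
        dx = np.zeros(x_shape, dtype=dy.dtype)
        # scatter one kernel offset at a time: 25/9 batched matmuls, no python
        # loop over samples or positions
        for i in range(kh):
            for j in range(kw):
                contrib = np.einsum("nfhw,fc->nchw", dy, w[:, :, i, j])
                dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += contrib
    return dw, db, dx


def maxpool_forward(x: np.ndarray, p: int):
    """Non-overlapping p x p max pool; trailing rows/cols are cropped."""
    n, c, h, w = x.shape
    hp, wp = h // p, w // p
    xr = x[:, :, : hp * p, : wp * p].reshape(n, c, hp, p, wp, p)
    patches = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp, wp, p * p)
    idx = patches.argmax(axis=-1)
    y = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool_backward(x_shape: tuple, idx: np.ndarray, p: int, dy: np.ndarray):
    n, c, h, w = x_shape
    hp, wp = h // p, w // p
    dpatches = np.zeros((n, c, hp, wp, p * p), dtype=dy.dtype)
    np.put_along_axis(dpatches, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, : hp * p, : wp * p] = (
        dpatches.reshape(n, c, hp, wp, p, p)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, hp * p, wp * p)
    )
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-300).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


@dataclass
class NetworkShapes:
    conv_out: list  # (C, H, W) after each conv (pre-pool)
    pool_out: list  # (C, H, W) after each pool
    flat: int
    dense_in: list


class Network:
    """CNN: [conv -> ReLU -> maxpool] x2 -> dense(ReLU) -> +hint ->
    dense(leaky ReLU) -> dense -> softmax.

    The 6 task-hint bits are concatenated with the first dense layer's output
    to form the input of the second dense layer.
    """

    N_HINT = 6
    N_CLASSES = 2

    def __init__(
        self,
        conv_specs: tuple,
        dense_widths: tuple,
        input_shape: tuple = (129, 191),
        leaky_slope: float = 0.1,
        use_hints: bool = True,
    ):
        if len(conv_specs) != 2:
            raise ValueError("exactly 2 convolutional layers are required")
        if len(dense_widths) != 3 or dense_widths[-1] != self.N_CLASSES:
            raise ValueError("exactly 3 dense layers with output width 2 required")
        self.conv_specs = tuple(
            cs if isinstance(cs, ConvSpec) else ConvSpec(**cs) for cs in conv_specs
        )
        self.dense_widths = tuple(int(d) for d in dense_widths)
        self.input_shape = tuple(input_shape)
        self.leaky_slope = float(leaky_slope)
        self.use_hints = bool(use_hints)
        self.shapes = self._infer_shapes()

    def _infer_shapes(self) -> NetworkShapes:
        c, (h, w) = 1, self.input_shape
        conv_out, pool_out = [], []
        for cs in self.conv_specs:
            h = (h - cs.kernel) // cs.stride + 1
            w = (w - cs.kernel) // cs.stride + 1
            if h < 1 or w < 1:
                raise ValueError("convolution shrinks input below 1 pixel")
            c = cs.filters
            conv_out.append((c, h, w))
            h, w = h // cs.pool, w // cs.pool
            if h < 1 or w < 1:
                raise ValueError("pooling shrinks input below 1 pixel")
            pool_out.append((c, h, w))
        flat = c * h * w
        dense_in = [flat, self.dense_widths[0] + self.N_HINT, self.dense_widths[1]]
        return NetworkShapes(conv_out=conv_out, pool_out=pool_out, flat=flat, dense_in=dense_in)

    # -- parameters ---------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict:
        """Seeded uniform fan-in initialization; biases start at zero."""
        params: dict[str, np.ndarray] = {}
        c_in = 1
        for li, cs in enumerate(self.conv_specs, start=1):
            fan_in = c_in * cs.kernel * cs.kernel
            limit = 1.0 / np.sqrt(fan_in)
            params[f"conv{li}_w"] = rng.uniform(
                -limit, limit, size=(cs.filters, c_in, cs.kernel, cs.kernel)
            )
            params[f"conv{li}_b"] = np.zeros(cs.filters)
            c_in = cs.filters
        for li, (n_in, n_out) in enumerate(
            zip(self.shapes.dense_in, self.dense_widths), start=1
        ):
            limit = 1.0 / np.sqrt(n_in)
            params[f"dense{li}_w"] = rng.uniform(-limit, limit, size=(n_in, n_out))
            params[f"dense{li}_b"] = np.zeros(n_out)
        return params

    # -- forward / backward -------------------------------------------------

    def forward(self, params: dict, x: np.ndarray, hints: np.ndarray):
        """x (N, H, W) or (N, 1, H, W); hints (N, 6). Returns (probs, cache)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"input grid shape {x.shape[2:]} != expected {self.input_shape}"
            )
        hints = np.asarray(hints, dtype=float)
        if hints.shape != (x.shape[0], self.N_HINT):
            raise ValueError(f"hint shape {hints.shape} != ({x.shape[0]}, {self.N_HINT})")

        cache: dict = {"x": x, "hints": hints}
        a = x
        for li, cs in enumerate(self.conv_specs, start=1):
            z, windows = conv2d_forward(a, params[f"conv{li}_w"], params[f"conv{li}_b"], cs.stride)
            relu = np.maximum(z, 0.0)
            pooled, idx = maxpool_forward(relu, cs.pool)
            cache[f"conv{li}_in_shape"] = a.shape
            cache[f"conv{li}_windows"] = windows
            cache[f"conv{li}_z"] = z
            cache[f"conv{li}_relu"] = relu
            cache[f"pool{li}_idx"] = idx
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        cache["flat"] = flat
        cache["pooled_shape"] = a.shape

        z1 = flat @ params["dense1_w"] + params["dense1_b"]
        h1 = np.maximum(z1, 0.0)
        hint_in = hints if self.use_hints else np.zeros_like(hints)
        h1c = np.concatenate([h1, hint_in], axis=1)
        z2 = h1c @ params["dense2_w"] + params["dense2_b"]
        h2 = np.where(z2 > 0, z2, self.leaky_slope * z2)
        logits = h2 @ params["dense3_w"] + params["dense3_b"]
        cache.update(z1=z1, h1=h1, h1c=h1c, z2=z2, h2=h2, logits=logits)
        return softmax(logits), cache

    def backward(self, params: dict, cache: dict, dlogits: np.ndarray, need_dx: bool = False):
        """Backpropagate dlogits. Returns (grads, d_conv2_relu, dx).

        ``d_conv2_relu`` is the gradient w.r.t. the last convolutional layer's
        rectified feature maps -- the quantity class-activation saliency needs.
        """
        grads: dict[str, np.ndarray] = {}
        grads["dense3_w"] = cache["h2"].T @ dlogits
        grads["dense3_b"] = dlogits.sum(axis=0)
        dh2 = dlogits @ params["dense3_w"].T
        dz2 = dh2 * np.where(cache["z2"] > 0, 1.0, self.leaky_slope)
        grads["dense2_w"] = cache["h1c"].T @ dz2
        grads["dense2_b"] = dz2.sum(axis=0)
        dh1c = dz2 @ params["dense2_w"].T
        dh1 = dh1c[:, : self.dense_widths[0]]
        dz1 = dh1 * (cache["z1"] > 0)
        grads["dense1_w"] = cache["flat"].T @ dz1
        grads["dense1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ params["dense1_w"].T
        da = dflat.reshape(cache["pooled_shape"])

        d_conv2_relu = None
        dx = None
        for li in (2, 1):
            cs = self.conv_specs[li - 1]
            relu_shape = cache[f"conv{li}_relu"].shape
            drelu = maxpool_backward(relu_shape, cache[f"pool{li}_idx"], cs.pool, da)
            if li == 2:
                d_conv2_relu = drelu
            dz = drelu * (cache[f"conv{li}_z"] > 0)
            dw, db, da = conv2d_backward(
                cache[f"conv{li}_in_shape"],
                cache[f"conv{li}_windows"],
                params[f"conv{li}_w"],
                cs.stride,
                dz,
                need_dx=(li > 1) or need_dx,
            )
            grads[f"conv{li}_w"] = dw
            grads[f"conv{li}_b"] = db
        dx = da
        return grads, d_conv2_relu, dx


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
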