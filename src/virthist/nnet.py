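"""Minimal CPU convolutional-network stack with manual backpropagation.

Implements exactly the pieces the style-transfer networks need -- valid
convolutions (via BLAS-backed tensor contractions), fractionally-strided
(transposed) convolutions, reflection/zero padding, instance normalization,
ReLU / leaky-ReLU / tanh -- plus the Adam optimizer.  All tensors are
``(C, H, W)`` float64 arrays for a single image (the training procedure uses
batch size 1 throughout).

Each ``forward`` returns ``(y, cache)`` so a network can appear several
times in one computation graph (the cycle-consistency pass applies each
generator twice); ``backward(dy, cache)`` returns the input gradient and
accumulates parameter gradients into ``layer.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2d", "ReflectionPad2d", "ZeroPad2d",
    "InstanceNorm2d", "ReLU", "LeakyReLU", "Tanh", "Sequential",
    "ResidualBlock", "Adam", "init_normal",
]


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(C, Ho, Wo, k, k) sliding windows of a (C, H, W) tensor."""
    v = sliding_window_view(x, (k, k), axis=(1, 2))
    return v[:, ::stride, ::stride]


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x):
        raise NotImplementedError

    def backward(self, dy, cache):
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def named_layers(self):
        yield self


def init_normal(rng: np.random.Generator, shape, sigma: float = 0.02) -> np.ndarray:
    """Gaussian weight initialization (mean 0, sigma 0.02 by convention)."""
    return rng.normal(0.0, sigma, size=shape)


class Conv2d(Layer):
    """Valid convolution (pad externally) with stride; weight (Co, Ci, k, k)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None, sigma: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.params["W"] = init_normal(rng, (cout, cin, k, k), sigma)
        self.params["b"] = np.zeros(cout)
        self.zero_grad()

    def forward(self, x):
        v = _windows(x, self.k, self.stride)
        y = np.tensordot(self.params["W"], v, axes=([1, 2, 3], [0, 3, 4]))
        y += self.params["b"][:, None, None]
        return y, (x, v.shape)

    def backward(self, dy, cache):
        x, vshape = cache
        k, s = self.k, self.stride
        v = _windows(x, k, s)
        self.grads["W"] += np.tensordot(dy, v, axes=([1, 2], [1, 2]))
        self.grads["b"] += dy.sum(axis=(1, 2))
        _, ho, wo = dy.shape
        dx = np.zeros_like(x)
        W = self.params["W"]
        for p in range(k):
            for q in range(k):
                dx[:, p:p + s * ho:s, q:q + s * wo:s] += np.tensordot(
                    W[:, :, p, q], dy, axes=([0], [0])
                )
        return dx


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; weight (Ci, Co, k, k).

    Output size is ``(H-1)*stride - 2*pad + k + output_padding`` per axis
    (the usual deconvolution convention); with k=3, stride=2, pad=1,
    output_padding=1 it exactly doubles the spatial size.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None, sigma: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if output_padding > pad:
            raise ValueError("output_padding must not exceed pad")
        self.k, self.stride, self.pad, self.opad = k, stride, pad, output_padding
        self.params["W"] = init_normal(rng, (cin, cout, k, k), sigma)
        self.params["b"] = np.zeros(cout)
        self.zero_grad()

    def _full_shape(self, h: int, w: int) -> tuple[int, int]:
        return (h - 1) * self.stride + self.k, (w - 1) * self.stride + self.k

    def forward(self, x):
        cin, h, w = x.shape
        cout = self.params["W"].shape[1]
        hp, wp = self._full_shape(h, w)
        y_full = np.zeros((cout, hp, wp))
        W = self.params["W"]
        s = self.stride
        for p in range(self.k):
            for q in range(self.k):
                y_full[:, p:p + s * h:s, q:q + s * w:s] += np.tensordot(
                    W[:, :, p, q], x, axes=([0], [0])
                )
        hout = (h - 1) * s - 2 * self.pad + self.k + self.opad
        wout = (w - 1) * s - 2 * self.pad + self.k + self.opad
        y = y_full[:, self.pad:self.pad + hout, self.pad:self.pad + wout].copy()
        y += self.params["b"][:, None, None]
        return y, (x, (hout, wout))

    def backward(self, dy, cache):
        x, (hout, wout) = cache
        cin, h, w = x.shape
        cout = dy.shape[0]
        hp, wp = self._full_shape(h, w)
        dfull = np.zeros((cout, hp, wp))
        dfull[:, self.pad:self.pad + hout, self.pad:self.pad + wout] = dy
        v = _windows(dfull, self.k, self.stride)  # (Co, H, W, k, k)
        W = self.params["W"]
        self.grads["W"] += np.tensordot(x, v, axes=([1, 2], [1, 2]))
        self.grads["b"] += dy.sum(axis=(1, 2))
        dx = np.tensordot(W, v, axes=([1, 2, 3], [0, 3, 4]))
        return dx


class ReflectionPad2d(Layer):
    def __init__(self, pad: int):
        super().__init__()
        self.pad = pad

    def forward(self, x):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p)), mode="reflect"), x.shape

    def backward(self, dy, cache):
        _, h, w = cache
        p = self.pad
        ri = np.pad(np.arange(h), p, mode="reflect")
        ci = np.pad(np.arange(w), p, mode="reflect")
        dx = np.zeros(cache)
        np.add.at(
            dx,
            (np.arange(cache[0])[:, None, None], ri[None, :, None], ci[None, None, :]),
            dy,
        )
        return dx


class ZeroPad2d(Layer):
    def __init__(self, pad: int):
        super().__init__()
        self.pad = pad

    def forward(self, x):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p), (p, p))), x.shape

    def backward(self, dy, cache):
        p = self.pad
        return dy[:, p:-p, p:-p].copy()


class InstanceNorm2d(Layer):
    """Per-channel spatial standardization (no learned affine)."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        m = xhat.shape[1] * xhat.shape[2]
        dmean = dy.mean(axis=(1, 2), keepdims=True)
        dproj = (dy * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (dy - dmean - xhat * dproj)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache):
        return dy * (1.0 - cache ** 2)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x):
        tape = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            tape.append(cache)
        return x, tape

    def backward(self, dy, cache):
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            dy = layer.backward(dy, c)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_layers(self):
        for layer in self.layers:
            yield from layer.named_layers()

    def __call__(self, x):
        """Convenience inference call discarding the tape."""
        y, _ = self.forward(x)
        return y


class ResidualBlock(Layer):
    """x + body(x); body must preserve the tensor shape."""

    def __init__(self, body: Sequential):
        super().__init__()
        self.body = body

    def forward(self, x):
        y, tape = self.body.forward(x)
        return x + y, tape

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)

    def zero_grad(self) -> None:
        self.body.zero_grad()

    def named_layers(self):
        yield from self.body.named_layers()


def parameter_count(net: Layer) -> int:
    return sum(p.size for layer in net.named_layers() for p in layer.params.values())


class Adam:
    """Adam over the parameters of one or more networks (batch size 1)."""

    def __init__(self, nets, lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        if not isinstance(nets, (list, tuple)):
            nets = [nets]
        self.entries = [
            (layer, name)
            for net in nets
            for layer in net.named_layers()
            for name in layer.params
        ]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in self.entries]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in self.entries]

    def zero_grad(self) -> None:
        for layer, name in self.entries:
            layer.grads[name] = np.zeros_like(layer.params[name])

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
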