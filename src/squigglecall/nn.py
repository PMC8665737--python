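"""Trainable layer objects with hand-derived gradients.

The base-calling network is small enough that a full autograd engine is
unnecessary: every layer is a :class:`Module` with an explicit
``forward``/``backward`` pair, and composite blocks route gradients
through their branches by hand.  All activations flow as ``(B, T, C)``
arrays (batch, time, channels); parameters are float64 throughout.

Weight layouts match :mod:`squigglecall.conv_ops` exactly — full and
fat-pointwise kernels are ``(Cout, D, Cin)``, depthwise kernels
``(D, C)``, compression ``(Cy, x, C)`` and decompression ``(C, x, Cy)``
— so the functional operators there serve as the reference
implementation for each layer's forward pass.

Every ``backward`` here is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv1d",
    "DepthwiseConv1d",
    "CompressConv1d",
    "DecompressConv1d",
    "BatchNorm1d",
    "Swish",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Minimal layer interface: forward caches what backward needs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _pad_time(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (0, 0)))


class Conv1d(Module):
    """Full 1-D convolution, odd depth, centred zero padding.

    Stride ``s`` maps length T to ``ceil(T / s)``.  Depth 1 is the
    pointwise convolution; small odd depth with Cin→Cout mixing is the
    fat-pointwise operation.
    """

    def __init__(self, cin: int, cout: int, depth: int, stride: int = 1):
        if depth % 2 == 0:
            raise ValueError(f"full convolution requires odd depth, got {depth}")
        self.cin, self.cout, self.depth, self.stride = cin, cout, depth, stride
        self.W = Parameter(np.zeros((cout, depth, cin)))
        self.B = Parameter(np.zeros(cout))

    def out_len(self, t: int) -> int:
        return -(-t // self.stride)

    def forward(self, x, train=False):
        b, t, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"Conv1d: got {cin} channels, expected {self.cin}")
        pad = self.depth // 2
        xp = _pad_time(x, pad)
        self._xp, self._t = xp, t
        to = self.out_len(t)
        out = np.broadcast_to(self.B.data, (b, to, self.cout)).copy()
        s = self.stride
        for d in range(self.depth):
            out += xp[:, d:d + (to - 1) * s + 1:s, :] @ self.W.data[:, d, :].T
        return out

    def backward(self, dy):
        xp, t = self._xp, self._t
        to = dy.shape[1]
        pad, s = self.depth // 2, self.stride
        self.B.grad += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, self.cout)
        for d in range(self.depth):
            sl = slice(d, d + (to - 1) * s + 1, s)
            xs = np.ascontiguousarray(xp[:, sl, :]).reshape(-1, self.cin)
            self.W.grad[:, d, :] += dyf.T @ xs
            dxp[:, sl, :] += dy @ self.W.data[:, d, :]
        return dxp[:, pad:pad + t, :] if pad else dxp


class DepthwiseConv1d(Module):
    """Per-channel convolution with dilation; stride 1, length preserving."""

    def __init__(self, c: int, depth: int, dilation: int = 1):
        self.c, self.depth, self.dilation = c, depth, dilation
        self.W = Parameter(np.zeros((depth, c)))
        self.B = Parameter(np.zeros(c))

    def forward(self, x, train=False):
        b, t, c = x.shape
        if c != self.c:
            raise ValueError(f"DepthwiseConv1d: got {c} channels, expected {self.c}")
        pad = (self.depth // 2) * self.dilation
        xp = _pad_time(x, pad)
        self._xp, self._t = xp, t
        out = np.broadcast_to(self.B.data, (b, t, c)).copy()
        for d in range(self.depth):
            off = d * self.dilation
            out += xp[:, off:off + t, :] * self.W.data[d]
        return out

    def backward(self, dy):
        xp, t = self._xp, self._t
        pad = (self.depth // 2) * self.dilation
        self.B.grad += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for d in range(self.depth):
            off = d * self.dilation
            self.W.grad[d] += (dy * xp[:, off:off + t, :]).sum(axis=(0, 1))
            dxp[:, off:off + t, :] += dy * self.W.data[d]
        return dxp[:, pad:pad + t, :] if pad else dxp


class CompressConv1d(Module):
    """Depth-to-space compression: depth == stride == x, (T, C) → (T/x, C*y).

    T not divisible by x is right-padded with zeros; the original length
    is remembered so the matching decompression can trim.
    """

    def __init__(self, c: int, x: int, y: int):
        self.c, self.x, self.y = c, x, y
        self.cy = c * y
        self.W = Parameter(np.zeros((self.cy, x, c)))
        self.B = Parameter(np.zeros(self.cy))

    def forward(self, x_in, train=False):
        b, t, c = x_in.shape
        if c != self.c:
            raise ValueError(f"CompressConv1d: got {c} channels, expected {self.c}")
        rem = (-t) % self.x
        if rem:
            x_in = np.pad(x_in, ((0, 0), (0, rem), (0, 0)))
        self._t_orig, self._t_pad = t, x_in.shape[1]
        ts = x_in.shape[1] // self.x
        win = x_in.reshape(b, ts, self.x * self.c)
        self._win = win
        return win @ self.W.data.reshape(self.cy, -1).T + self.B.data

    def backward(self, dy):
        b, ts, _ = dy.shape
        self.B.grad += dy.sum(axis=(0, 1))
        wmat = self.W.data.reshape(self.cy, -1)
        dyf = dy.reshape(-1, self.cy)
        self.W.grad += (dyf.T @ self._win.reshape(-1, self.x * self.c)
                        ).reshape(self.W.shape)
        dwin = dy @ wmat
        dx = dwin.reshape(b, self._t_pad, self.c)
        return dx[:, :self._t_orig, :]


class DecompressConv1d(Module):
    """Strided transposed convolution inverting the compression shape:
    (T/x, Cy) → (T, C), depth == stride so writes never overlap."""

    def __init__(self, c: int, x: int, cy: int):
        self.c, self.x, self.cy = c, x, cy
        self.W = Parameter(np.zeros((c, x, cy)))
        self.B = Parameter(np.zeros(c))

    def forward(self, z, train=False):
        b, ts, cy = z.shape
        if cy != self.cy:
            raise ValueError(f"DecompressConv1d: got {cy} channels, expected {self.cy}")
        self._z = z
        out = z @ self.W.data.reshape(self.c * self.x, cy).T
        out = out.reshape(b, ts, self.c, self.x).transpose(0, 1, 3, 2)
        return out.reshape(b, ts * self.x, self.c) + self.B.data

    def backward(self, dy):
        b, t, c = dy.shape
        ts = t // self.x
        self.B.grad += dy.sum(axis=(0, 1))
        dyr = np.ascontiguousarray(
            dy.reshape(b, ts, self.x, c).transpose(0, 1, 3, 2)
        ).reshape(b, ts, -1)
        self.W.grad += (dyr.reshape(-1, c * self.x).T @ self._z.reshape(-1, self.cy)
                        ).reshape(self.W.shape)
        return dyr @ self.W.data.reshape(self.c * self.x, self.cy)


class BatchNorm1d(Module):
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, c: int, epsilon: float = 1e-5, momentum: float = 0.1):
        self.c, self.epsilon, self.momentum = c, epsilon, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=False):
        if x.shape[2] != self.c:
            raise ValueError(f"BatchNorm1d: got {x.shape[2]} channels, expected {self.c}")
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            self._train = True
        else:
            mean, var = self.running_mean, self.running_var
            self._train = False
        self._inv_std = 1.0 / np.sqrt(var + self.epsilon)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.data
        if not self._train:
            return dxhat * inv_std
        n = dy.shape[0] * dy.shape[1]
        # standard batch-norm backward through the batch statistics
        return (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class Swish(Module):
    """x * sigmoid(x)."""

    def forward(self, x, train=False):
        from scipy.special import expit

        s = expit(x)
        self._x, self._s = x, s
        return x * s

    def backward(self, dy):
        s = self._s
        return dy * (s + self._x * s * (1.0 - s))
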