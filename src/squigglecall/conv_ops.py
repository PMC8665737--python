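"""1-D convolution factorizations on (T, C) time-by-channel tensors.

All operators here are pure functions on NumPy arrays of shape
``(T, C)`` — ``T`` timesteps by ``C`` channels — and implement the exact
defining sums of the factorizations used throughout the base-calling
network:

* full convolution of odd depth ``D``;
* depthwise convolution (per-channel, optionally dilated);
* pointwise convolution (channel mixing at a single timestep);
* separable convolution (depthwise then pointwise);
* k-blueprint-separable convolution: a "fat" pointwise convolution of
  depth ``k`` followed by a ``k``-dilated depthwise convolution, which
  keeps a receptive field of ``D`` while shrinking the depthwise kernel
  by a factor of ``k``;
* strided depth-to-space compression (``x`` timesteps of ``C`` channels
  to one timestep of ``C*y`` channels) and its transposed inverse.

Every operator is length-preserving at stride 1 (zero padding centred on
the output timestep); the compression pair divides/multiplies length by
exactly the stride.  Trainable layer wrappers with gradients live in
:mod:`squigglecall.nn`; these functions are the ground-truth reference
they are tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FullConvParams",
    "DepthwiseParams",
    "PointwiseParams",
    "FatPointwiseParams",
    "BatchNormParams",
    "full_conv",
    "depthwise_conv",
    "pointwise_conv",
    "separable_conv",
    "k_blueprint_separable_conv",
    "strided_compress_conv",
    "transposed_decompress_conv",
    "batch_norm",
    "swish",
    "count_params_and_flops",
]


def _as_tc(x) -> np.ndarray:
    """Validate and return ``x`` as a finite float (T, C) matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"expected a (T, C) matrix, got shape {x.shape}")
    if x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError(f"need T >= 1 and C >= 1, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input tensor contains non-finite entries")
    return x


@dataclass
class FullConvParams:
    """Weights of a full convolution: ``W[j, d, i]`` maps input channel
    ``i`` at kernel offset ``d`` to output channel ``j``; ``B[j]`` is the
    bias.  Depth ``D = W.shape[1]`` must be odd."""

    W: np.ndarray  # (Cout, D, Cin)
    B: np.ndarray  # (Cout,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.W.ndim != 3:
            raise ValueError(f"full-conv W must be (Cout, D, Cin), got {self.W.shape}")
        if self.depth % 2 == 0:
            raise ValueError(
                f"full convolution requires odd depth D, got D={self.depth}"
            )
        if self.B.shape != (self.W.shape[0],):
            raise ValueError(f"bias shape {self.B.shape} != (Cout,)={self.W.shape[0]}")

    @property
    def depth(self) -> int:
        return self.W.shape[1]


@dataclass
class DepthwiseParams:
    """Per-channel kernel ``W[d, j]`` with optional dilation."""

    W: np.ndarray  # (depth', C)
    B: np.ndarray  # (C,)
    dilation: int = 1

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.W.ndim != 2:
            raise ValueError(f"depthwise W must be (depth', C), got {self.W.shape}")
        if self.B.shape != (self.W.shape[1],):
            raise ValueError(f"bias shape {self.B.shape} != (C,)={self.W.shape[1]}")
        if int(self.dilation) < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        self.dilation = int(self.dilation)

    @property
    def depth(self) -> int:
        return self.W.shape[0]


@dataclass
class PointwiseParams:
    """Channel-mixing matrix ``W[j, i]`` applied at each timestep."""

    W: np.ndarray  # (Cout, Cin)
    B: np.ndarray  # (Cout,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.W.ndim != 2:
            raise ValueError(f"pointwise W must be (Cout, Cin), got {self.W.shape}")
        if self.B.shape != (self.W.shape[0],):
            raise ValueError(f"bias shape {self.B.shape} != (Cout,)={self.W.shape[0]}")


@dataclass
class FatPointwiseParams:
    """A standard convolution of small odd depth ``k`` — the channel-mixing
    half of the k-blueprint-separable factorization."""

    W: np.ndarray  # (Cout, k, Cin)
    B: np.ndarray  # (Cout,)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.W.ndim != 3:
            raise ValueError(
                f"fat-pointwise W must be (Cout, k, Cin), got {self.W.shape}"
            )
        if self.k % 2 == 0:
            raise ValueError(f"fat-pointwise depth k must be odd, got k={self.k}")
        if self.B.shape != (self.W.shape[0],):
            raise ValueError(f"bias shape {self.B.shape} != (Cout,)={self.W.shape[0]}")

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass
class BatchNormParams:
    """Per-channel affine normalization statistics and parameters."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    epsilon: float = 1e-5
    momentum: float = 0.1  # EMA weight of the current batch in train mode

    def __post_init__(self):
        for name in ("gamma", "beta", "running_mean", "running_var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.gamma.shape == self.beta.shape == self.running_mean.shape
                == self.running_var.shape):
            raise ValueError("batch-norm parameter vectors must share shape (C,)")
        if np.any(self.running_var < 0):
            raise ValueError("running variance must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def identity(cls, c: int, epsilon: float = 1e-5) -> "BatchNormParams":
        """gamma=1, beta=0, mean=0, var=1 — an (almost) exact identity."""
        return cls(np.ones(c), np.zeros(c), np.zeros(c), np.ones(c), epsilon)


def _check_channels(x: np.ndarray, cin: int, what: str) -> None:
    if x.shape[1] != cin:
        raise ValueError(
            f"{what}: input has {x.shape[1]} channels but parameters expect {cin}"
        )


def full_conv(x, p: FullConvParams) -> np.ndarray:
    """Full 1-D convolution of odd depth D.

    The input is zero-padded with ``D // 2`` timesteps on each side, so
    ``Y[t, j] = sum_{d, i} Xpad[t + d, i] * W[j, d, i] + B[j]`` and the
    output keeps length T; output timestep ``t`` is centred on input
    timestep ``t``.
    """
    x = _as_tc(x)
    cout, d, cin = p.W.shape
    _check_channels(x, cin, "full_conv")
    t = x.shape[0]
    pad = d // 2
    xp = np.pad(x, ((pad, pad), (0, 0)))
    out = np.empty((t, cout))
    out[:] = p.B
    for off in range(d):
        out += xp[off:off + t] @ p.W[:, off, :].T
    return out


def depthwise_conv(x, p: DepthwiseParams) -> np.ndarray:
    """Per-channel (optionally dilated) convolution.

    Padding is ``(depth' // 2) * dilation`` zeros on each side, so
    ``Y[t, j] = sum_d Xpad[t + d*dilation, j] * W[d, j] + B[j]`` keeps
    length T and stays centred.
    """
    x = _as_tc(x)
    depth, c = p.W.shape
    _check_channels(x, c, "depthwise_conv")
    t = x.shape[0]
    pad = (depth // 2) * p.dilation
    xp = np.pad(x, ((pad, pad), (0, 0)))
    out = np.tile(p.B, (t, 1))
    for d in range(depth):
        out += xp[d * p.dilation:d * p.dilation + t] * p.W[d]
    return out


def pointwise_conv(x, p: PointwiseParams) -> np.ndarray:
    """Channel mixing at each timestep: ``Y[t, j] = sum_i X[t, i] W[j, i] + B[j]``."""
    x = _as_tc(x)
    _check_channels(x, p.W.shape[1], "pointwise_conv")
    return x @ p.W.T + p.B


def separable_conv(x, dp: DepthwiseParams, pp: PointwiseParams) -> np.ndarray:
    """Depthwise-then-pointwise approximation of a full convolution."""
    if dp.dilation != 1:
        raise ValueError("separable convolution uses an undilated depthwise step")
    return pointwise_conv(depthwise_conv(x, dp), pp)


def fat_pointwise_conv(x, p: FatPointwiseParams) -> np.ndarray:
    """Depth-k standard convolution (padding k // 2 each side)."""
    return full_conv(x, FullConvParams(p.W, p.B))


def k_blueprint_separable_conv(
    x, fp: FatPointwiseParams, dp: DepthwiseParams
) -> np.ndarray:
    """Fat-pointwise (depth k) followed by a k-dilated depthwise step.

    With depthwise depth ``D/k`` and dilation ``k`` the composition has a
    total receptive field of ``D`` — the same as a full convolution of
    depth D — while the depthwise kernel is k times shorter.  ``k = 1``
    recovers the ordinary blueprint-separable convolution (pointwise
    first, then depthwise).
    """
    k = fp.k
    if dp.dilation != k:
        raise ValueError(
            f"k-blueprint-separable: depthwise dilation ({dp.dilation}) must "
            f"equal the fat-pointwise depth k ({k})"
        )
    receptive = dp.depth * k
    if dp.depth % 2 == 0:
        warnings.warn(
            f"depthwise depth D/k = {dp.depth} is even: the receptive field of "
            f"the k-separable convolution (D = {receptive}) is asymmetric",
            stacklevel=2,
        )
    z = fat_pointwise_conv(x, fp)
    return depthwise_conv(z, dp)


def strided_compress_conv(x, W, B, stride: int) -> np.ndarray:
    """Depth-to-space compression: a convolution with depth == stride == x.

    Takes ``x`` consecutive samples of C channels and emits one sample of
    ``Cy`` channels: output shape ``(T/x, Cy)``.  If T is not a multiple
    of the stride the signal is right-padded with zeros to the next
    multiple (the caller is expected to trim after decompression).
    """
    x_in = _as_tc(x)
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    if W.ndim != 3 or W.shape[1] != stride:
        raise ValueError(f"compression W must be (Cy, x={stride}, C), got {W.shape}")
    cy, _, c = W.shape
    _check_channels(x_in, c, "strided_compress_conv")
    t = x_in.shape[0]
    rem = (-t) % stride
    if rem:
        x_in = np.pad(x_in, ((0, rem), (0, 0)))
    ts = x_in.shape[0] // stride
    # non-overlapping windows: reshape, then contract depth and channels
    windows = x_in.reshape(ts, stride * c)
    return windows @ W.reshape(cy, stride * c).T + B


def transposed_decompress_conv(z, W, B, stride: int) -> np.ndarray:
    """Inverse-shaped strided transposed convolution.

    Each compressed sample spreads over ``stride`` output timesteps
    (depth == stride, so the writes do not overlap):
    ``out[s*x + d, j] = sum_i Z[s, i] W[j, d, i] + B[j]``.
    """
    z = _as_tc(z)
    W = np.asarray(W, dtype=float)
    B = np.asarray(B, dtype=float)
    if W.ndim != 3 or W.shape[1] != stride:
        raise ValueError(f"decompression W must be (C, x={stride}, Cy), got {W.shape}")
    c, _, cy = W.shape
    _check_channels(z, cy, "transposed_decompress_conv")
    ts = z.shape[0]
    out = z @ W.reshape(c * stride, cy).T  # (Ts, C*x) with j-major, d-minor? no:
    # W.reshape(c*stride, cy) stacks (j, d) pairs row-major, so column block
    # layout below must match: out[s, j*stride + d].
    out = out.reshape(ts, c, stride).transpose(0, 2, 1).reshape(ts * stride, c)
    return out + B


def batch_norm(x, p: BatchNormParams, mode: str = "infer") -> np.ndarray:
    """Per-channel normalization.

    ``infer`` uses the stored running statistics; ``train`` normalizes by
    the batch statistics of ``x`` and updates the running statistics in
    place by exponential moving average.
    """
    x = _as_tc(x)
    _check_channels(x, p.gamma.shape[0], "batch_norm")
    if mode == "infer":
        mean, var = p.running_mean, p.running_var
    elif mode == "train":
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        m = p.momentum
        p.running_mean *= 1 - m
        p.running_mean += m * mean
        p.running_var *= 1 - m
        p.running_var += m * var
    else:
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    return p.gamma * (x - mean) / np.sqrt(var + p.epsilon) + p.beta


def swish(x) -> np.ndarray:
    """Elementwise Swish activation, ``x * sigmoid(x)``."""
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    return x * expit(x)


def count_params_and_flops(
    kind: str,
    *,
    cin: int,
    cout: int | None = None,
    depth: int = 1,
    k: int = 1,
    t: int = 1,
    include_bias: bool = False,
) -> dict:
    """Closed-form weight-parameter and flop counts per layer kind.

    ``flops`` counts multiplications for ``t`` timesteps (``flops_per_t``
    is the per-timestep figure).  Kinds: ``full``, ``depthwise``,
    ``pointwise``, ``separable``, ``k_blueprint_separable``,
    ``compress``, ``decompress``.

    * full:       params ``Cout*D*Cin``, flops ``T*Cout*D*Cin``
    * separable:  params ``D*Cin + Cout*Cin``, flops ``T*(D*Cin + Cout*Cin)``
    * k-bsc:      params ``Cout*k*Cin + (D/k)*Cout``
    """
    if cout is None:
        cout = cin
    if kind == "full":
        params = cout * depth * cin
        flops_per_t = cout * depth * cin
        biases = cout
    elif kind == "depthwise":
        params = depth * cin
        flops_per_t = depth * cin
        biases = cin
    elif kind == "pointwise":
        return count_params_and_flops(
            "full", cin=cin, cout=cout, depth=1, t=t, include_bias=include_bias
        )
    elif kind == "separable":
        params = depth * cin + cout * cin
        flops_per_t = depth * cin + cout * cin
        biases = cin + cout
    elif kind == "k_blueprint_separable":
        if depth % k:
            raise ValueError(f"depth D={depth} must be divisible by k={k}")
        params = cout * k * cin + (depth // k) * cout
        flops_per_t = cout * k * cin + (depth // k) * cout
        biases = cout + cout
    elif kind == "compress":
        # depth == stride == x, non-overlapping: flops per *input* timestep
        params = cout * depth * cin
        flops_per_t = cout * cin  # Cout*x*Cin mults per output step, /x steps
        biases = cout
    elif kind == "decompress":
        params = cout * depth * cin
        flops_per_t = cout * cin
        biases = cout
    else:
        raise ValueError(f"unknown layer kind {kind!r}")
    if include_bias:
        params += biases
    return {"params": int(params), "flops_per_t": int(flops_per_t),
            "flops": int(t * flops_per_t)}
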