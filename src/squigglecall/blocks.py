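"""Composite network blocks and their initialization.

Three block families make up the base-calling network:

* :class:`CBlock` — convolution + batch norm + (optional) Swish;
* :class:`ResidualBlockBonito` — the classic QuartzNet-style residual
  block: R separable-convolution sub-blocks on the main branch (the last
  without activation), a pointwise+BN skip branch, summed and activated;
* :class:`ResidualBlockCompressed` — the redesigned residual block: the
  first separable convolution is replaced by a depth-to-space compression
  (x timesteps of C channels → one timestep of C·y channels), the R−2
  inner convolutions are k-blueprint-separable at the compressed
  resolution, a plain depthwise operation precedes the decompression,
  and a strided transposed convolution restores (T, C).  Shape-wise it
  is a drop-in replacement for the Bonito block.

Identity initialization sets every depthwise kernel in the compressed
main branch to a centred delta and every fat-pointwise kernel to a
centred identity channel map plus uniform noise U(−ε, ε), so that at
ε = 0 each inner sub-block's linear+normalization path is an exact
identity map at initialization.  All other layers fall back to
Glorot-uniform U(−b, b) with b = sqrt(6 / (Cin + Cout)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm1d,
    CompressConv1d,
    Conv1d,
    DecompressConv1d,
    DepthwiseConv1d,
    Module,
    Parameter,
    Swish,
)

__all__ = [
    "IdentityInitSpec",
    "SeparableConv1d",
    "KSepConv1d",
    "CBlock",
    "ResidualBlockBonito",
    "ResidualBlockCompressed",
    "glorot_init",
    "identity_init",
    "nearest_odd",
]


@dataclass
class IdentityInitSpec:
    """How to initialize the compressed main branch.

    epsilon
        Half-width of the uniform perturbation added to the diagonal of
        fat-pointwise kernels; 0 gives an exact identity.
    init_depthwise, init_fat_pointwise
        Which halves of the k-separable convolutions receive the identity
        treatment (both, by default; disabling both reduces to Glorot).
    """

    epsilon: float = 0.02
    init_depthwise: bool = True
    init_fat_pointwise: bool = True

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @staticmethod
    def glorot_bound(cin: int, cout: int) -> float:
        return float(np.sqrt(6.0 / (cin + cout)))


def nearest_odd(v: float) -> int:
    """Nearest odd integer ≥ 1 (ties round up)."""
    n = max(1, int(round(v)))
    if n % 2 == 0:
        n += 1 if v >= n else -1
    return max(1, n)


class SeparableConv1d(Module):
    """Depthwise (depth D) then pointwise (Cin → Cout)."""

    def __init__(self, cin: int, cout: int, depth: int):
        self.dw = DepthwiseConv1d(cin, depth)
        self.pw = Conv1d(cin, cout, 1)

    def forward(self, x, train=False):
        return self.pw.forward(self.dw.forward(x, train), train)

    def backward(self, dy):
        return self.dw.backward(self.pw.backward(dy))


class KSepConv1d(Module):
    """k-blueprint-separable convolution as a trainable layer.

    Fat-pointwise convolution of depth k (Cin → Cout) followed by a
    k-dilated depthwise convolution of depth D/k; total receptive field D.
    """

    def __init__(self, cin: int, cout: int, depth: int, k: int):
        if k % 2 == 0:
            raise ValueError(f"k must be odd, got {k}")
        if depth % k:
            raise ValueError(f"depth D={depth} must be divisible by k={k}")
        if (depth // k) % 2 == 0:
            warnings.warn(
                f"D/k = {depth // k} is even: receptive field is asymmetric",
                stacklevel=2,
            )
        self.depth, self.k = depth, k
        self.fat = Conv1d(cin, cout, k)
        self.dw = DepthwiseConv1d(cout, depth // k, dilation=k)

    def forward(self, x, train=False):
        return self.dw.forward(self.fat.forward(x, train), train)

    def backward(self, dy):
        return self.fat.backward(self.dw.backward(dy))


_CONV_KINDS = ("full", "separable", "k_blueprint_separable")


class CBlock(Module):
    """Convolution + batch norm + Swish (activation optional).

    ``stride`` (full convolutions only) reduces length T to ceil(T/s).
    """

    def __init__(self, cin: int, cout: int, depth: int, *, stride: int = 1,
                 conv_kind: str = "full", k: int = 3, activation: bool = True):
        if conv_kind not in _CONV_KINDS:
            raise ValueError(f"conv_kind must be one of {_CONV_KINDS}")
        if conv_kind != "full" and stride != 1:
            raise ValueError("stride > 1 is only supported for full convolutions")
        if conv_kind == "full":
            self.conv = Conv1d(cin, cout, depth, stride=stride)
        elif conv_kind == "separable":
            self.conv = SeparableConv1d(cin, cout, depth)
        else:
            self.conv = KSepConv1d(cin, cout, depth, k)
        self.bn = BatchNorm1d(cout)
        self.act = Swish() if activation else None

    def forward(self, x, train=False):
        y = self.bn.forward(self.conv.forward(x, train), train)
        return self.act.forward(y, train) if self.act is not None else y

    def backward(self, dy):
        if self.act is not None:
            dy = self.act.backward(dy)
        return self.conv.backward(self.bn.backward(dy))


class ResidualBlockBonito(Module):
    """QuartzNet/Bonito-style residual block, (T, C) → (T, C).

    Main branch: R separable-conv sub-blocks, the last omitting the
    activation.  Skip branch: pointwise convolution + batch norm.  The
    branches are summed and Swish is applied.
    """

    def __init__(self, c: int, depth: int, r: int):
        if r < 1:
            raise ValueError("need at least one main-branch sub-block")
        self.sub = [
            CBlock(c, c, depth, conv_kind="separable", activation=(i < r - 1))
            for i in range(r)
        ]
        self.skip_pw = Conv1d(c, c, 1)
        self.skip_bn = BatchNorm1d(c)
        self.out_act = Swish()

    def forward(self, x, train=False):
        main = x
        for blk in self.sub:
            main = blk.forward(main, train)
        skip = self.skip_bn.forward(self.skip_pw.forward(x, train), train)
        if main.shape != skip.shape:
            raise ValueError(
                f"branch shape mismatch: main {main.shape} vs skip {skip.shape}"
            )
        return self.out_act.forward(main + skip, train)

    def backward(self, dy):
        dsum = self.out_act.backward(dy)
        dmain = dsum
        for blk in reversed(self.sub):
            dmain = blk.backward(dmain)
        dskip = self.skip_pw.backward(self.skip_bn.backward(dsum))
        return dmain + dskip


class ResidualBlockCompressed(Module):
    """Residual block with depth-to-space compression, (T, C) → (T, C).

    Main branch: compression (T, C) → (T/x, C·y); R−2 k-blueprint-
    separable sub-blocks at the compressed resolution (depth ``depth``,
    dilation step k); one depthwise operation (depth ≈ depth/x, rounded
    to odd) + BN without activation; decompression back to (T, C) + BN.
    Skip branch: pointwise + BN at full resolution.  Sum, then Swish.

    ``inner_activation=False`` drops the Swish inside the inner
    sub-blocks, leaving their linear+BN path — used to verify the
    identity-initialization property.
    """

    def __init__(self, c: int, depth: int, r: int, *, k: int = 3, x: int = 3,
                 y: int = 2, inner_activation: bool = True):
        if r < 3:
            raise ValueError(f"compressed block needs R >= 3 (R−2 inner convs), got {r}")
        self.c, self.x, self.y = c, x, y
        cy = c * y
        self.compress = CompressConv1d(c, x, y)
        self.inner = [
            CBlock(cy, cy, depth, conv_kind="k_blueprint_separable", k=k,
                   activation=inner_activation)
            for _ in range(r - 2)
        ]
        self.pre_dw = DepthwiseConv1d(cy, nearest_odd(depth / x))
        self.pre_bn = BatchNorm1d(cy)
        self.decompress = DecompressConv1d(c, x, cy)
        self.post_bn = BatchNorm1d(c)
        self.skip_pw = Conv1d(c, c, 1)
        self.skip_bn = BatchNorm1d(c)
        self.out_act = Swish()

    def forward(self, x, train=False):
        t = x.shape[1]
        z = self.compress.forward(x, train)
        for blk in self.inner:
            z = blk.forward(z, train)
        z = self.pre_bn.forward(self.pre_dw.forward(z, train), train)
        main = self.post_bn.forward(self.decompress.forward(z, train), train)
        self._trim = main.shape[1] - t  # zero unless T % x != 0
        main = main[:, :t, :]
        skip = self.skip_bn.forward(self.skip_pw.forward(x, train), train)
        return self.out_act.forward(main + skip, train)

    def backward(self, dy):
        dsum = self.out_act.backward(dy)
        dmain = dsum
        if self._trim:
            dmain = np.pad(dmain, ((0, 0), (0, self._trim), (0, 0)))
        dz = self.decompress.backward(self.post_bn.backward(dmain))
        dz = self.pre_dw.backward(self.pre_bn.backward(dz))
        for blk in reversed(self.inner):
            dz = blk.backward(dz)
        dx = self.compress.backward(dz)
        dskip = self.skip_pw.backward(self.skip_bn.backward(dsum))
        return dx + dskip


def _glorot_fill(param: Parameter, cin: int, cout: int, rng: np.random.Generator):
    bound = IdentityInitSpec.glorot_bound(cin, cout)
    param.data[...] = rng.uniform(-bound, bound, size=param.shape)


def glorot_init(module: Module, rng: np.random.Generator) -> None:
    """Glorot-uniform weights (bound sqrt(6/(Cin+Cout))), zero biases,
    identity batch norms.  Applied recursively, deterministic given rng."""
    if isinstance(module, Conv1d):
        _glorot_fill(module.W, module.cin, module.cout, rng)
        module.B.data[...] = 0.0
    elif isinstance(module, DepthwiseConv1d):
        _glorot_fill(module.W, module.c, module.c, rng)
        module.B.data[...] = 0.0
    elif isinstance(module, CompressConv1d):
        _glorot_fill(module.W, module.c, module.cy, rng)
        module.B.data[...] = 0.0
    elif isinstance(module, DecompressConv1d):
        _glorot_fill(module.W, module.cy, module.c, rng)
        module.B.data[...] = 0.0
    elif isinstance(module, BatchNorm1d):
        module.gamma.data[...] = 1.0
        module.beta.data[...] = 0.0
        module.running_mean[...] = 0.0
        module.running_var[...] = 1.0
    else:
        for val in vars(module).values():
            if isinstance(val, Module):
                glorot_init(val, rng)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        glorot_init(item, rng)


def _identity_fat_pointwise(conv: Conv1d, epsilon: float,
                            rng: np.random.Generator) -> None:
    """W[j, d, i] = δ_{⌊k/2⌋, d} (δ_{ij} + U(−ε, ε)); identity restricted to
    the leading min(Cin, Cout) diagonal when the layer is not square."""
    conv.W.data[...] = 0.0
    center = conv.depth // 2
    m = min(conv.cin, conv.cout)
    eye = np.zeros((conv.cout, conv.cin))
    eye[np.arange(m), np.arange(m)] = 1.0
    noise = rng.uniform(-epsilon, epsilon, size=(conv.cout, conv.cin)) if epsilon else 0.0
    conv.W.data[:, center, :] = eye + noise
    conv.B.data[...] = 0.0


def _identity_depthwise(dw: DepthwiseConv1d) -> None:
    """W[d, j] = δ_{⌊depth/2⌋, d} — a centred delta on every channel."""
    dw.W.data[...] = 0.0
    dw.W.data[dw.depth // 2, :] = 1.0
    dw.B.data[...] = 0.0


def identity_init(block: Module, spec: IdentityInitSpec,
                  rng: np.random.Generator) -> None:
    """Near-identity initialization of the compressed main branch.

    Every k-separable convolution inside a :class:`ResidualBlockCompressed`
    (and its pre-decompression depthwise operation) is set to near-identity
    per ``spec``; compression, decompression, skip and everything else get
    the Glorot fallback.  For any other module the call reduces to
    :func:`glorot_init`.  Deterministic given the rng state.
    """
    glorot_init(block, rng)
    if isinstance(block, KSepConv1d):
        if spec.init_fat_pointwise:
            _identity_fat_pointwise(block.fat, spec.epsilon, rng)
        if spec.init_depthwise:
            _identity_depthwise(block.dw)
    elif isinstance(block, ResidualBlockCompressed):
        for cblk in block.inner:
            if spec.init_fat_pointwise:
                _identity_fat_pointwise(cblk.conv.fat, spec.epsilon, rng)
            if spec.init_depthwise:
                _identity_depthwise(cblk.conv.dw)
        if spec.init_depthwise:
            _identity_depthwise(block.pre_dw)
    else:
        for val in vars(block).values():
            items = val if isinstance(val, (list, tuple)) else [val]
            for item in items:
                if isinstance(item, (KSepConv1d, ResidualBlockCompressed)):
                    identity_init(item, spec, rng)
                elif isinstance(item, Module) and not isinstance(
                    item, (Conv1d, DepthwiseConv1d, CompressConv1d,
                           DecompressConv1d, BatchNorm1d)
                ):
                    identity_init(item, spec, rng)
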