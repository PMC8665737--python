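"""Model assembly: config → CNN → per-frame base posteriors.

The network follows the CNN-CTC base-caller topology: a strided C-type
head that downsamples the raw signal (overall stride 3, so a window of
T samples yields T' = ceil(T/3) output frames), a stack of residual
blocks (compressed or Bonito-style), one or two C-type tail blocks, and
a decoder that projects to five channels — A, C, G, T, blank — and
applies a row-wise softmax.  Configurations are plain YAML; two are
shipped: ``default`` (desk-trainable) and ``large`` (a wider, deeper
stand-in closer to a production base caller).

Weights serialize to a single ``.npz`` archive of named float64 tensors
plus a JSON manifest (names, shapes, layer kinds, config); the round
trip is bit-exact.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
import yaml

from . import blocks as blk
from . import nn
from .blocks import IdentityInitSpec

__all__ = [
    "ModelConfig",
    "PosteriorMatrix",
    "Decoder",
    "Model",
    "build_model",
    "batch_forward",
    "save_model",
    "load_model",
]

N_OUT = 5  # A, C, G, T, blank


@dataclass
class PosteriorMatrix:
    """(T', 5) per-frame probability distributions over {A, C, G, T, −}."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_OUT:
            raise ValueError(f"posterior must be (T', 5), got {self.probs.shape}")
        if np.any(self.probs < -1e-9) or np.any(self.probs > 1 + 1e-9):
            raise ValueError("posterior entries must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise ValueError("posterior rows must sum to 1 within 1e-6")

    def __len__(self):
        return self.probs.shape[0]


class ModelConfig:
    """Ordered block list plus the input channel count.

    Block dicts (see ``configs/*.yaml``):

    * ``{type: c, cout, depth, stride?, conv_kind, k?}``
    * ``{type: residual_compressed, c, depth, r, k, x, y}``
    * ``{type: residual_bonito, c, depth, r}``
    * ``{type: decoder, cout: 5}`` (must be last, must emit 5 channels)

    The channel hand-off between consecutive blocks is validated at
    construction and any inconsistency is reported with the offending
    block index.
    """

    def __init__(self, blocks_spec: list[dict], in_channels: int = 1):
        self.in_channels = int(in_channels)
        self.blocks_spec = [dict(b) for b in blocks_spec]
        self._validate()

    def _validate(self):
        if not self.blocks_spec:
            raise ValueError("model config needs at least a decoder block")
        c = self.in_channels
        for i, b in enumerate(self.blocks_spec):
            btype = b.get("type")
            if btype == "c":
                if int(b.get("cin", c)) != c:
                    raise ValueError(
                        f"block {i} (c): expects {b['cin']} input channels, "
                        f"previous block emits {c}"
                    )
                c = int(b["cout"])
            elif btype in ("residual_compressed", "residual_bonito"):
                if int(b["c"]) != c:
                    raise ValueError(
                        f"block {i} ({btype}): operates on {b['c']} channels, "
                        f"previous block emits {c}"
                    )
            elif btype == "decoder":
                if i != len(self.blocks_spec) - 1:
                    raise ValueError(f"block {i}: decoder must be the last block")
                if int(b.get("cout", N_OUT)) != N_OUT:
                    raise ValueError(
                        f"block {i} (decoder): must emit {N_OUT} channels "
                        f"(A, C, G, T, blank), config says {b.get('cout')}"
                    )
            else:
                raise ValueError(f"block {i}: unknown block type {btype!r}")
        if self.blocks_spec[-1].get("type") != "decoder":
            raise ValueError("the last block must be the decoder")

    @property
    def total_stride(self) -> int:
        s = 1
        for b in self.blocks_spec:
            s *= int(b.get("stride", 1))
        return s

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "blocks": self.blocks_spec}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(d["blocks"], in_channels=d.get("in_channels", 1))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def named(cls, name: str) -> "ModelConfig":
        """Load a shipped configuration (``default``, ``large``, ``tiny``)."""
        ref = importlib.resources.files("squigglecall") / "configs" / f"{name}.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls.named("default")


class Decoder(nn.Module):
    """Pointwise projection to 5 channels followed by a row-wise
    log-softmax; ``exp`` of the output is the posterior matrix."""

    def __init__(self, cin: int):
        self.pw = nn.Conv1d(cin, N_OUT, 1)

    def forward(self, x, train=False):
        logits = self.pw.forward(x, train)
        m = logits.max(axis=2, keepdims=True)
        z = logits - m
        logp = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
        self._softmax = np.exp(logp)
        return logp

    def backward(self, dlogp):
        dlogits = dlogp - self._softmax * dlogp.sum(axis=2, keepdims=True)
        return self.pw.backward(dlogits)


def _build_block(spec: dict) -> nn.Module:
    btype = spec["type"]
    if btype == "c":
        return blk.CBlock(
            int(spec["cin"]), int(spec["cout"]), int(spec["depth"]),
            stride=int(spec.get("stride", 1)),
            conv_kind=spec.get("conv_kind", "full"),
            k=int(spec.get("k", 3)),
            activation=bool(spec.get("activation", True)),
        )
    if btype == "residual_compressed":
        return blk.ResidualBlockCompressed(
            int(spec["c"]), int(spec["depth"]), int(spec["r"]),
            k=int(spec.get("k", 3)), x=int(spec.get("x", 3)),
            y=int(spec.get("y", 2)),
        )
    if btype == "residual_bonito":
        return blk.ResidualBlockBonito(int(spec["c"]), int(spec["depth"]),
                                       int(spec["r"]))
    if btype == "decoder":
        return Decoder(int(spec["cin"]))
    raise ValueError(f"unknown block type {btype!r}")


class Model(nn.Module):
    """The full base-calling network.

    ``forward_logp`` is the training path: batched (B, T, C) input to
    (B, T', 5) log-posteriors with gradients.  ``forward`` is the
    user-facing inference path: one normalized signal to a
    :class:`PosteriorMatrix`.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        c = config.in_channels
        specs = []
        for b in config.blocks_spec:
            s = dict(b)
            if b["type"] in ("c", "decoder"):
                s["cin"] = c
                c = int(b.get("cout", N_OUT))
            specs.append(s)
        self.blocks = [_build_block(s) for s in specs]

    # -- construction ---------------------------------------------------
    def init_params(self, init: str = "identity",
                    spec: IdentityInitSpec | None = None,
                    seed: int = 0) -> "Model":
        """Initialize all parameters; ``init`` is ``identity`` (compressed
        main branches near-identity, everything else Glorot) or
        ``glorot``.  Deterministic given the seed."""
        rng = np.random.default_rng(seed)
        if init == "identity":
            blk.identity_init(self, spec or IdentityInitSpec(), rng)
        elif init == "glorot":
            blk.glorot_init(self, rng)
        else:
            raise ValueError(f"init must be 'identity' or 'glorot', got {init!r}")
        return self

    # -- shape algebra --------------------------------------------------
    @property
    def total_stride(self) -> int:
        return self.config.total_stride

    def out_len(self, t: int) -> int:
        for b in self.config.blocks_spec:
            t = -(-t // int(b.get("stride", 1)))
        return t

    @property
    def chunk_alignment(self) -> int:
        """Sample granularity at which the network is shift-equivariant:
        the total stride times every depth-to-space compression factor
        (chunk windows must start on multiples of this)."""
        a = self.total_stride
        for b in self.config.blocks_spec:
            if b["type"] == "residual_compressed":
                a = int(np.lcm(a, self.total_stride * int(b.get("x", 3))))
        return a

    @property
    def receptive_field(self) -> int:
        """Span of input samples influencing one output frame (an upper
        bound used as the minimum accepted signal length)."""
        rf, jump = 1, 1
        for b in self.config.blocks_spec:
            btype = b["type"]
            if btype == "c":
                d = int(b["depth"])
                rf += (d - 1) * jump
                jump *= int(b.get("stride", 1))
            elif btype == "residual_bonito":
                rf += int(b["r"]) * (int(b["depth"]) - 1) * jump
            elif btype == "residual_compressed":
                x = int(b.get("x", 3))
                rf += (x - 1) * jump
                inner_jump = jump * x
                span = int(b["depth"])  # fat-pointwise + dilated depthwise
                rf += (int(b["r"]) - 2) * (span - 1) * inner_jump
                rf += (blk.nearest_odd(b["depth"] / x) - 1) * inner_jump
        return rf

    # -- computation ----------------------------------------------------
    def forward_logp(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for b in self.blocks:
            x = b.forward(x, train=train)
        return x

    def backward(self, dlogp: np.ndarray) -> np.ndarray:
        for b in reversed(self.blocks):
            dlogp = b.backward(dlogp)
        return dlogp

    def forward(self, signal: np.ndarray, train: bool = False) -> PosteriorMatrix:
        """Normalized signal (T,) — or (T, C) with extra input channels —
        to a posterior matrix of length ceil(T / total stride)."""
        sig = np.asarray(signal, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.shape[0] < self.receptive_field:
            raise ValueError(
                f"signal of length {sig.shape[0]} is shorter than the "
                f"receptive field; need at least {self.receptive_field} samples"
            )
        logp = self.forward_logp(sig[None], train=train)[0]
        return PosteriorMatrix(np.exp(logp))

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def astype(self, dtype) -> "Model":
        """Cast parameters, gradients and batch-norm statistics in place
        (float32 roughly halves training time; float64 is the default
        and is what the serialization format stores)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for _, bn in _chain_bns(self):
            bn.running_mean = bn.running_mean.astype(dtype)
            bn.running_var = bn.running_var.astype(dtype)
        return self


def build_model(config: ModelConfig | None = None, *, init: str = "identity",
                init_spec: IdentityInitSpec | None = None, seed: int = 0) -> Model:
    """Construct and initialize a model (default config if none given)."""
    return Model(config or ModelConfig.default()).init_params(init, init_spec, seed)


def batch_forward(model: Model, signals, *, window: int = 9999,
                  overlap: int | None = None) -> list[PosteriorMatrix]:
    """Run inference on arbitrarily long signals by chunking.

    Signals longer than ``window`` samples are split into overlapping
    windows; each window's posterior keeps only its interior frames
    (overlap halves discarded), so the stitched posterior has exactly
    ceil(T / stride) frames and interior frames match an unchunked run.
    ``window`` and ``overlap`` must be multiples of the model stride;
    the default overlap is 5% of the window, rounded to the stride.
    """
    st = model.total_stride
    align = model.chunk_alignment
    window = (window // align) * align
    if overlap is None:
        overlap = max(align, round(0.05 * window / align) * align)
    if window % align or overlap % align:
        raise ValueError(
            f"window and overlap must be multiples of the chunk alignment {align}"
        )
    if window <= 2 * overlap:
        raise ValueError("window must exceed twice the overlap")
    step = window - 2 * overlap
    out = []
    for sig in signals:
        sig = np.asarray(sig, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        t = sig.shape[0]
        if t <= window:
            out.append(model.forward(sig))
            continue
        n_frames = -(-t // st)
        stitched = np.empty((n_frames, N_OUT))
        start = 0
        while True:
            last = start + window >= t
            # chunk starts stay on the alignment grid so the compression
            # phase and frame indices line up with the unchunked run
            s0 = (-(-(t - window) // align)) * align if last else start
            chunk = sig[s0:min(s0 + window, t)]
            probs = model.forward(chunk).probs
            g0 = 0 if start == 0 else (s0 + overlap) // st
            g1 = n_frames if last else (s0 + window - overlap) // st
            stitched[g0:g1] = probs[g0 - s0 // st:g1 - s0 // st]
            if last:
                break
            start += step
        out.append(PosteriorMatrix(stitched))
    return out


def save_model(model: Model, path) -> None:
    """Single-file archive: named float64 tensors + JSON manifest
    (names, shapes, layer kinds, config).  Bit-exact round trip."""
    arrays, manifest = {}, {"config": model.config.to_dict(), "tensors": []}
    for name, p in model.named_parameters():
        key = f"param/{name}"
        arrays[key] = p.data
        manifest["tensors"].append(
            {"name": key, "shape": list(p.data.shape), "kind": "parameter"}
        )
    for i, b in enumerate(model.blocks):
        for bn_name, bn in _batch_norms(b, f"blocks.{i}."):
            for stat in ("running_mean", "running_var"):
                key = f"stat/{bn_name}{stat}"
                arrays[key] = getattr(bn, stat)
                manifest["tensors"].append(
                    {"name": key, "shape": [bn.c], "kind": "bn_stat"}
                )
    arrays["__manifest__"] = np.array(json.dumps(manifest))
    np.savez(path, **arrays)


def _batch_norms(module: nn.Module, prefix: str):
    for name, val in vars(module).items():
        if isinstance(val, nn.BatchNorm1d):
            yield f"{prefix}{name}.", val
        elif isinstance(val, nn.Module):
            yield from _batch_norms(val, f"{prefix}{name}.")
        elif isinstance(val, (list, tuple)):
            for i, item in enumerate(val):
                if isinstance(item, nn.Module):
                    yield from _batch_norms(item, f"{prefix}{name}.{i}.")


def load_model(path) -> Model:
    with np.load(path, allow_pickle=False) as arch:
        manifest = json.loads(str(arch["__manifest__"]))
        model = Model(ModelConfig.from_dict(manifest["config"]))
        params = dict(model.named_parameters())
        for entry in manifest["tensors"]:
            key = entry["name"]
            if entry["kind"] == "parameter":
                pname = key[len("param/"):]
                if pname not in params:
                    raise ValueError(f"archive tensor {key} has no matching parameter")
                params[pname].data = arch[key].copy()
                params[pname].grad = np.zeros_like(params[pname].data)
        stats = {n: bn for n, bn in _chain_bns(model)}
        for entry in manifest["tensors"]:
            if entry["kind"] == "bn_stat":
                name = entry["name"][len("stat/"):]
                bn_name, stat = name.rsplit(".", 1)
                setattr(stats[bn_name + "."], stat, arch[entry["name"]].copy())
    return model


def _chain_bns(model: Model):
    for i, b in enumerate(model.blocks):
        yield from _batch_norms(b, f"blocks.{i}.")
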