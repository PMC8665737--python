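"""Desk-scale training, the read-accuracy metric, and three experiments.

Training minimizes the CTC loss with Adam on fixed-length signal chunks
cut at ground-truth event boundaries from simulated reads.  Everything
is seeded: batch order, chunk sampling and initialization are all
deterministic functions of the training config.

Read accuracy follows the standard base-calling definition: one minus
the ratio of the alignment edit distance to the base-call length,
floored at zero, with the median reported over reads.  Reads whose call
is empty are excluded from the accuracy list and counted as unmapped
(there is no aligner here, so "mapped" means "nonempty call").

The three experiments replicate, on synthetic data, three observations
about what makes base calling hard:

* ``ablation_identity_init`` — identity versus Glorot initialization of
  the compressed main branches at a fixed small training budget;
* ``experiment_boundary_input`` — feeding the ground-truth event
  boundaries as a second input channel (diagnostic only: a real base
  caller cannot see them) and measuring how much faster a fixed
  accuracy threshold is reached;
* ``experiment_purine_probe`` — a logistic regression on ground-truth
  event means separating purines {A, G} from pyrimidines {C, T}.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import edlib
import numpy as np

from .ctc import best_path_decode, ctc_loss_batch
from .network import Model, ModelConfig, batch_forward, build_model
from .squiggle_sim import SquiggleRead, event_means, normalize, purine_labels

__all__ = [
    "TrainConfig",
    "AccuracyReport",
    "TrainingDiverged",
    "read_accuracy",
    "train",
    "basecall_reads",
    "evaluate",
    "split_reads",
    "ablation_identity_init",
    "experiment_boundary_input",
    "experiment_purine_probe",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Training hyper-parameters; recorded verbatim in every report."""

    optimizer: str = "adam"
    lr: float = 2e-3
    lr_schedule: str = "cosine"  # or "constant"; cosine decays to 5% of lr
    warmup_steps: int = 20
    batch_size: int = 16
    steps: int = 300
    seed: int = 0
    init: str = "identity"  # or "glorot"
    boundary_channel: bool = False
    chunk_len: int = 432  # signal samples per training chunk
    dtype: str = "float32"  # training compute precision
    eval_every: int = 0  # 0 = no mid-training evaluation
    eval_reads: int = 24
    eval_window: int = 3000

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.init not in ("identity", "glorot"):
            raise ValueError("init must be 'identity' or 'glorot'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    def lr_at(self, step: int) -> float:
        """Learning rate for 0-based ``step``: linear warmup, then either
        constant or a cosine decay to 5% of the peak."""
        warm = min(1.0, (step + 1) / max(1, self.warmup_steps))
        if self.lr_schedule == "constant":
            return self.lr * warm
        frac = step / max(1, self.steps - 1)
        return self.lr * warm * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))


@dataclass
class AccuracyReport:
    """Per-read accuracies, their median and the mapped fraction."""

    accuracies: list[float]
    median: float
    mapped_fraction: float
    n_reads: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def read_accuracy(call: str, reference: str) -> float:
    """1 − editDistance(call, reference) / |call|, floored at 0.

    The denominator is the call length (not the reference length); unit
    edit costs (Levenshtein).  An empty call has no defined accuracy —
    callers treat it as unmapped.
    """
    if not call:
        raise ValueError("accuracy of an empty call is undefined; count it unmapped")
    dist = edlib.align(call, reference)["editDistance"]
    return max(0.0, 1.0 - dist / len(call))


def split_reads(reads: list[SquiggleRead], held_out_fraction: float = 0.2):
    """Deterministic train/held-out split by read-id hash (CRC32)."""
    buckets = round(1.0 / held_out_fraction)
    train_r, held = [], []
    for r in reads:
        (held if zlib.crc32(r.id.encode()) % buckets == 0 else train_r).append(r)
    return train_r, held


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class _ChunkSampler:
    """Cuts fixed-length training chunks at event boundaries.

    A chunk is a run of whole events starting at a random event,
    truncated to at most ``chunk_len`` samples and zero-padded to
    exactly ``chunk_len``; its label is the spanned bases.  Signals are
    normalized per read, once.
    """

    def __init__(self, reads, chunk_len: int, boundary_channel: bool):
        self.chunk_len = chunk_len
        self.channels = 2 if boundary_channel else 1
        self.items = []
        for r in reads:
            sig = normalize(r.signal)
            starts = np.flatnonzero(r.boundaries)
            ends = np.append(starts[1:], len(sig))
            self.items.append((r, sig, starts, ends))

    def sample(self, rng: np.random.Generator):
        for _ in range(20):
            r, sig, starts, ends = self.items[rng.integers(len(self.items))]
            e0 = int(rng.integers(len(starts)))
            s0 = starts[e0]
            e1 = int(np.searchsorted(ends, s0 + self.chunk_len, side="right")) - 1
            if e1 < e0:
                continue  # single event longer than the chunk; rare
            span = int(ends[e1] - s0)
            x = np.zeros((self.chunk_len, self.channels))
            x[:span, 0] = sig[s0:s0 + span]
            if self.channels == 2:
                x[:span, 1] = r.boundaries[s0:s0 + span]
            return x, r.sequence[e0:e1 + 1], span
        raise RuntimeError("could not sample a chunk; chunk_len too small?")


@dataclass
class TrainResult:
    model: Model
    loss_curve: list[float]
    eval_steps: list[int]
    eval_medians: list[float]
    config: TrainConfig


def train(reads: list[SquiggleRead], cfg: TrainConfig,
          config: ModelConfig | None = None,
          eval_reads: list[SquiggleRead] | None = None,
          stop_at_median: float | None = None) -> TrainResult:
    """Train a model on simulated reads with the CTC loss.

    If ``cfg.eval_every`` > 0 and evaluation reads are supplied, the
    held-out median read accuracy is recorded periodically;
    ``stop_at_median`` stops early once that median is reached (used by
    the steps-to-threshold experiment).
    """
    mcfg = config or ModelConfig.default()
    if cfg.boundary_channel and mcfg.in_channels != 2:
        d = mcfg.to_dict()
        d["in_channels"] = 2
        mcfg = ModelConfig.from_dict(d)
    model = build_model(mcfg, init=cfg.init, seed=cfg.seed)
    if cfg.dtype != "float64":
        model.astype(cfg.dtype)
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = _Adam(model.parameters(), cfg.lr)
    sampler = _ChunkSampler(reads, cfg.chunk_len, cfg.boundary_channel)
    rng = np.random.default_rng(cfg.seed + 1)
    st = model.total_stride

    losses, eval_steps, eval_medians = [], [], []
    for step in range(cfg.steps):
        batch, labels, spans = [], [], []
        for _ in range(cfg.batch_size):
            x, lab, span = sampler.sample(rng)
            batch.append(x)
            labels.append(lab)
            spans.append(span)
        xb = np.stack(batch).astype(cfg.dtype)
        logp = model.forward_logp(xb, train=True)
        vf = -(-np.asarray(spans) // st)
        item_losses, grads = ctc_loss_batch(logp, labels, vf)
        ok = np.isfinite(item_losses)
        if not ok.any():
            raise TrainingDiverged("no feasible CTC alignments in the batch")
        n_ok = int(ok.sum())
        loss = float(item_losses[ok].sum() / n_ok)
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"loss became non-finite at step {step} (lr={cfg.lr})"
            )
        model.zero_grad()
        model.backward((grads / n_ok).astype(cfg.dtype))
        opt.lr = cfg.lr_at(step)
        opt.step()
        losses.append(loss)

        if cfg.eval_every and eval_reads and (step + 1) % cfg.eval_every == 0:
            rep = evaluate(model, eval_reads[:cfg.eval_reads],
                           window=cfg.eval_window,
                           boundary_channel=cfg.boundary_channel)
            eval_steps.append(step + 1)
            eval_medians.append(rep.median)
            if stop_at_median is not None and rep.median >= stop_at_median:
                break
    return TrainResult(model, losses, eval_steps, eval_medians, cfg)


def basecall_reads(model: Model, reads: list[SquiggleRead], *,
                   window: int = 6000, boundary_channel: bool = False):
    """Normalize, run chunked inference and greedy-decode each read."""
    signals = []
    for r in reads:
        sig = normalize(r.signal)
        if boundary_channel:
            sig = np.stack([sig, r.boundaries.astype(float)], axis=1)
        signals.append(sig)
    posteriors = batch_forward(model, signals, window=window)
    return [(r.id, best_path_decode(p.probs)) for r, p in zip(reads, posteriors)]


def evaluate(model: Model, reads: list[SquiggleRead], *, window: int = 6000,
             boundary_channel: bool = False, meta: dict | None = None
             ) -> AccuracyReport:
    calls = basecall_reads(model, reads, window=window,
                           boundary_channel=boundary_channel)
    accs = [read_accuracy(call, r.sequence)
            for (rid, call), r in zip(calls, reads) if call]
    mapped = len(accs) / len(reads) if reads else 0.0
    median = float(np.median(accs)) if accs else 0.0
    return AccuracyReport(accs, median, mapped, len(reads), meta=meta or {})


def ablation_identity_init(reads, cfg: TrainConfig, seeds,
                           config: ModelConfig | None = None) -> dict:
    """Identity vs Glorot initialization at an identical training budget.

    Returns per-seed held-out medians for both arms plus a win/loss
    tally (identity wins a seed when its median is at least as high).
    """
    train_r, held = split_reads(reads)
    report = {"config": asdict(cfg), "seeds": list(map(int, seeds)),
              "identity": [], "glorot": []}
    for arm in ("identity", "glorot"):
        for seed in seeds:
            c = TrainConfig(**{**asdict(cfg), "init": arm, "seed": int(seed)})
            res = train(train_r, c, config=config)
            rep = evaluate(res.model, held[:cfg.eval_reads],
                           window=cfg.eval_window)
            report[arm].append(rep.median)
    wins = sum(1 for a, b in zip(report["identity"], report["glorot"]) if a >= b)
    report["identity_median"] = float(np.median(report["identity"]))
    report["glorot_median"] = float(np.median(report["glorot"]))
    report["identity_wins"] = wins
    return report


def experiment_boundary_input(reads, cfg: TrainConfig, seeds, *,
                              threshold: float = 0.5,
                              config: ModelConfig | None = None) -> dict:
    """Steps needed to reach a held-out median accuracy threshold, with
    and without the ground-truth event-boundary input channel.

    The boundary arm is diagnostic only: not usable for base calling,
    since real inference cannot access ground-truth boundaries.
    """
    if cfg.eval_every < 1:
        raise ValueError("experiment needs eval_every >= 1")
    train_r, held = split_reads(reads)
    report = {"config": asdict(cfg), "threshold": threshold,
              "seeds": list(map(int, seeds)),
              "note": "diagnostic-only: not usable for base calling",
              "baseline_steps": [], "boundary_steps": []}
    for arm, key in ((False, "baseline_steps"), (True, "boundary_steps")):
        for seed in seeds:
            c = TrainConfig(**{**asdict(cfg), "boundary_channel": arm,
                               "seed": int(seed)})
            res = train(train_r, c, config=config, eval_reads=held,
                        stop_at_median=threshold)
            reached = [s for s, m in zip(res.eval_steps, res.eval_medians)
                       if m >= threshold]
            report[key].append(reached[0] if reached else None)
    def _med(vals):
        vals = [v if v is not None else cfg.steps + cfg.eval_every for v in vals]
        return float(np.median(vals))
    report["baseline_median_steps"] = _med(report["baseline_steps"])
    report["boundary_median_steps"] = _med(report["boundary_steps"])
    return report


def experiment_purine_probe(reads: list[SquiggleRead], seed: int = 0,
                            shuffle_labels: bool = False) -> float:
    """Held-out accuracy of a one-feature logistic regression separating
    purine from pyrimidine events, given ground-truth segmentation.

    Event means are computed on the raw signals (the simulator emits
    them on a common scale; per-read renormalization would only move
    the class boundary around).  Half the events train the classifier
    and the other half are scored.  With shuffled labels the expected
    accuracy is 0.5 (the null)."""
    from sklearn.linear_model import LogisticRegression

    feats, labels = [], []
    for r in reads:
        feats.append(event_means(r))
        labels.append(purine_labels(r.sequence))
    x = np.concatenate(feats)[:, None]
    y = np.concatenate(labels)
    rng = np.random.default_rng(seed)
    if shuffle_labels:
        y = rng.permutation(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate dataset: only one base class present")
    order = rng.permutation(len(y))
    half = len(y) // 2
    tr, te = order[:half], order[half:]
    clf = LogisticRegression().fit(x[tr], y[tr])
    return float(clf.score(x[te], y[te]))
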