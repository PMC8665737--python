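"""Synthetic nanopore squiggle generator.

A nanopore sequencer reports the ionic current through a pore roughly
4000 times per second while DNA translocates at about 450 bases per
second, so each one-base shift of the pore context produces on average
~8.9 current samples, with large dwell-time variance.  The current
level itself is set by a short DNA context (5–12 bases) around the pore
head, different contexts can produce similar levels, and the readout is
noisy.  This module emulates exactly those features so the whole
base-calling pipeline can be trained and verified at desk scale with
known ground truth: every simulated read carries its true sequence,
per-base dwell times and per-sample event-boundary labels.

The pore model is additive: each of the ``context_length`` positions
contributes a per-base level term (strongest at the central position,
decaying with distance), plus a small seeded pairwise interaction
between the central base and its neighbours so that distinct contexts
occasionally collide to near-identical levels.  By construction the
central-position contribution separates purines {A, G} from pyrimidines
{C, T} by well over one noise standard deviation, which is what makes a
simple logistic regression on correctly segmented event means able to
tell the two classes apart.

What this simulator does *not* model: real R9.4.1 pore chemistry,
homopolymer-specific error structure, current drift, stalls, or adapter
signal.  Results on this data bound what the architecture can learn,
not real-read accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctc import ALPHABET

__all__ = [
    "PoreModel",
    "SquiggleRead",
    "random_sequence",
    "simulate",
    "normalize",
    "event_means",
    "export_dataset",
    "import_dataset",
]

SAMPLE_RATE = 4000.0  # signal samples per second
TRANSLOCATION_SPEED = 450.0  # bases per second
MEAN_DWELL = SAMPLE_RATE / TRANSLOCATION_SPEED  # ≈ 8.9 samples per base

_BASE_IDX = {b: i for i, b in enumerate(ALPHABET)}
_PURINES = frozenset("AG")


@dataclass
class PoreModel:
    """Additive context-to-level model plus dwell and noise parameters.

    ``level_table[p, b]`` is the contribution of base ``b`` at context
    position ``p`` (position ``context_length // 2`` is the base under
    the pore head).  ``interaction[b_center, b_neighbor, p]`` adds a
    small seeded coupling between the central base and each neighbour.
    Dwell times are 1 + NegativeBinomial with mean ``MEAN_DWELL`` and
    variance ``dwell_var_factor`` times the mean.  ``noise_sd`` is i.i.d.
    Gaussian readout noise per sample, in the same (normalized) units as
    the level table.
    """

    context_length: int = 6
    level_table: np.ndarray | None = None
    interaction: np.ndarray | None = None
    noise_sd: float = 0.25
    dwell_var_factor: float = 3.0
    table_seed: int = 7

    # central-position levels: purines high, pyrimidines low, ordered so
    # that every base remains individually resolvable
    _CENTRAL = (1.0, -0.6, 0.6, -1.0)  # A, C, G, T

    def __post_init__(self):
        if not 5 <= self.context_length <= 12:
            raise ValueError(
                f"context_length must be in [5, 12], got {self.context_length}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        c = self.context_length
        rng = np.random.default_rng(self.table_seed)
        if self.level_table is None:
            center = c // 2
            table = np.empty((c, 4))
            for p in range(c):
                if p == center:
                    table[p] = self._CENTRAL
                else:
                    scale = 0.3 / (1 + abs(p - center))
                    table[p] = rng.normal(0.0, scale, size=4)
            self.level_table = table
        else:
            self.level_table = np.asarray(self.level_table, dtype=float)
            if self.level_table.shape != (c, 4):
                raise ValueError(
                    f"level_table must be ({c}, 4), got {self.level_table.shape}"
                )
        if self.interaction is None:
            self.interaction = rng.uniform(-0.1, 0.1, size=(4, 4, c))
            self.interaction[:, :, c // 2] = 0.0
        center = c // 2
        pur = np.mean([self.level_table[center, _BASE_IDX[b]] for b in "AG"])
        pyr = np.mean([self.level_table[center, _BASE_IDX[b]] for b in "CT"])
        if abs(pur - pyr) < self.noise_sd:
            raise ValueError(
                "pore model degenerate: purine/pyrimidine central levels must "
                f"differ by at least one noise sd ({self.noise_sd}), got "
                f"{abs(pur - pyr):.3f}"
            )

    def event_level(self, seq: str, j: int) -> float:
        """Expected level while base ``j`` of ``seq`` is under the head.

        The context window is centred on ``j``; positions falling off the
        read contribute nothing (edge events are slightly attenuated).
        """
        c = self.context_length
        center = c // 2
        bj = _BASE_IDX[seq[j]]
        level = 0.0
        for p in range(c):
            q = j + p - center
            if 0 <= q < len(seq):
                bq = _BASE_IDX[seq[q]]
                level += self.level_table[p, bq]
                if p != center:
                    level += self.interaction[bj, bq, p]
        return level


@dataclass
class SquiggleRead:
    """One synthetic read with full ground truth."""

    id: str
    signal: np.ndarray  # raw (unnormalized) current series
    sequence: str
    dwell: np.ndarray  # samples per base, >= 1 each
    boundaries: np.ndarray  # binary; 1 at the first sample of each event
    noise_sd: float = 0.25

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.dwell = np.asarray(self.dwell, dtype=np.intp)
        self.boundaries = np.asarray(self.boundaries, dtype=np.int8)
        if self.dwell.sum() != len(self.signal):
            raise ValueError("dwell times must sum to the signal length")
        if np.any(self.dwell < 1):
            raise ValueError("every base must dwell for at least one sample")
        if int(self.boundaries.sum()) != len(self.sequence):
            raise ValueError("need exactly one boundary mark per base")


def random_sequence(length: int, seed=None) -> str:
    """Uniform i.i.d. DNA sequence, deterministic per seed."""
    rng = np.random.default_rng(seed)
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _draw_dwells(n: int, pore: PoreModel, rng: np.random.Generator) -> np.ndarray:
    """Shifted negative binomial: 1 + NB with mean MEAN_DWELL − 1 and
    variance ≈ dwell_var_factor × MEAN_DWELL (heavy-tailed, CV ≥ 0.4)."""
    m = MEAN_DWELL - 1.0
    v = pore.dwell_var_factor * MEAN_DWELL
    p = m / v
    r = m * m / (v - m)
    return 1 + rng.negative_binomial(r, p, size=n)


def simulate(seq: str, pore: PoreModel | None = None, seed=None,
             read_id: str = "read") -> SquiggleRead:
    """Simulate the squiggle for ``seq``.

    Each base dwells for a random number of samples; its samples sit at
    the context-determined level plus Gaussian noise.  Ground-truth dwell
    times and event boundaries are recorded alongside the signal.
    """
    pore = pore or PoreModel()
    if len(seq) < pore.context_length:
        raise ValueError(
            f"sequence length {len(seq)} < context length {pore.context_length}"
        )
    rng = np.random.default_rng(seed)
    n = len(seq)
    dwell = _draw_dwells(n, pore, rng)
    levels = np.array([pore.event_level(seq, j) for j in range(n)])
    signal = np.repeat(levels, dwell)
    signal = signal + rng.normal(0.0, pore.noise_sd, size=len(signal))
    boundaries = np.zeros(len(signal), dtype=np.int8)
    starts = np.concatenate([[0], np.cumsum(dwell)[:-1]])
    boundaries[starts] = 1
    return SquiggleRead(read_id, signal, seq, dwell, boundaries,
                        noise_sd=pore.noise_sd)


def normalize(signal: np.ndarray) -> np.ndarray:
    """Robust per-read normalization: (x − median) / (1.4826 · MAD).

    Affine-invariant: ``normalize(a*x + b) == sign(a) * normalize(x)``.
    Used identically at training and inference time.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 samples to normalize, got {x.size}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("degenerate signal: median absolute deviation is zero")
    return (x - med) / (1.4826 * mad)


def event_means(read: SquiggleRead) -> np.ndarray:
    """Mean signal level within each base's event (ground-truth segmentation)."""
    starts = np.flatnonzero(read.boundaries)
    ends = np.append(starts[1:], len(read.signal))
    sums = np.add.reduceat(read.signal, starts)
    return sums / (ends - starts)


def purine_labels(seq: str) -> np.ndarray:
    """1 for purines (A, G), 0 for pyrimidines (C, T)."""
    return np.array([1 if b in _PURINES else 0 for b in seq], dtype=np.int8)


def simulate_dataset(n_reads: int, pore: PoreModel | None = None, *,
                     min_len: int = 200, max_len: int = 1000,
                     seed: int = 0, prefix: str = "read") -> list[SquiggleRead]:
    """Simulate ``n_reads`` reads with lengths uniform in [min_len, max_len].

    Fully reproducible from (pore config, seed); each read gets an
    independent child seed so subsets are stable under reordering.
    """
    pore = pore or PoreModel()
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(min_len, max_len + 1))
        seq_seed, sim_seed = rng.integers(0, 2**31, size=2)
        seq = random_sequence(length, seq_seed)
        reads.append(simulate(seq, pore, sim_seed, read_id=f"{prefix}_{i:05d}"))
    return reads


def export_dataset(reads: list[SquiggleRead], signals_path, fasta_path,
                   meta_path, header: dict | None = None) -> None:
    """Write signals as TSV, references as FASTA and dwell/boundary
    ground truth as a JSON sidecar; :func:`import_dataset` round-trips
    bit-exactly (signals serialized with full float precision)."""
    from .io_cli import write_signals  # shared TSV format

    write_signals(signals_path, [(r.id, r.signal) for r in reads], header=header)
    with open(fasta_path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
    meta = {
        "header": header or {},
        "reads": {
            r.id: {"dwell": r.dwell.tolist(), "noise_sd": r.noise_sd}
            for r in reads
        },
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh)


def import_dataset(signals_path, fasta_path, meta_path) -> list[SquiggleRead]:
    from .io_cli import read_signals

    signals = dict(read_signals(signals_path))
    seqs = {}
    name = None
    for line in Path(fasta_path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line.strip()
    meta = json.loads(Path(meta_path).read_text())
    reads = []
    for rid, sig in signals.items():
        dwell = np.array(meta["reads"][rid]["dwell"], dtype=np.intp)
        boundaries = np.zeros(len(sig), dtype=np.int8)
        boundaries[np.concatenate([[0], np.cumsum(dwell)[:-1]])] = 1
        reads.append(SquiggleRead(rid, sig, seqs[rid], dwell, boundaries,
                                  noise_sd=meta["reads"][rid].get("noise_sd", 0.25)))
    return reads
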