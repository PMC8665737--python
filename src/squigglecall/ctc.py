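"""CTC loss and decoding over the {A, C, G, T, blank} alphabet.

The network emits one 5-way distribution per output frame; connectionist
temporal classification (CTC) marginalizes over every blank-augmented
alignment between the frame sequence and a DNA label, so training never
needs an explicit signal segmentation.  The loss is the standard CTC
forward recursion in log space (log-sum-exp throughout, safe for very
long frame sequences); its gradient with respect to the per-frame
log-posteriors is obtained from the forward/backward state posteriors
and is finite-difference-verified in the tests.

Decoding is greedy best-path by default — per-frame argmax, collapse
consecutive repeats, drop blanks — with an optional prefix beam search.
A brute-force path enumerator (feasible for T ≤ 8) serves as the
independent oracle the loss is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "ALPHABET",
    "BLANK",
    "CtcLossResult",
    "ctc_loss",
    "ctc_loss_batch",
    "best_path_decode",
    "beam_search_decode",
    "brute_force_ctc",
    "tie_break",
    "labels_to_indices",
    "min_frames",
]

ALPHABET = "ACGT"
BLANK = 4  # channel order A, C, G, T, blank

_NEG_INF = -np.inf


def labels_to_indices(label: str) -> np.ndarray:
    try:
        return np.array([ALPHABET.index(b) for b in label], dtype=np.intp)
    except ValueError:
        bad = sorted(set(label) - set(ALPHABET))
        raise ValueError(f"label contains non-ACGT symbols: {bad}") from None


def min_frames(label: str) -> int:
    """Frames required to emit ``label``: its length plus one blank
    between each pair of repeated bases."""
    reps = sum(1 for a, b in zip(label, label[1:]) if a == b)
    return len(label) + reps


@dataclass
class CtcLossResult:
    """Negative log alignment probability and its gradient with respect
    to the (T', 5) log-posterior matrix."""

    neg_log_prob: float
    grad: np.ndarray


def _extended(label_idx: np.ndarray) -> np.ndarray:
    """Blank-augmented state sequence −l1−l2−…−lL−."""
    ext = np.full(2 * len(label_idx) + 1, BLANK, dtype=np.intp)
    ext[1::2] = label_idx
    return ext


def ctc_loss(log_posteriors: np.ndarray, label: str) -> CtcLossResult:
    """CTC negative log-likelihood of ``label`` given per-frame
    log-probabilities, with gradient.

    An infeasible label (more required frames than available) yields an
    infinite loss and a zero gradient rather than an exception.
    """
    lp = np.asarray(log_posteriors, dtype=float)
    if lp.ndim != 2 or lp.shape[1] != 5:
        raise ValueError(f"log_posteriors must be (T', 5), got {lp.shape}")
    t_frames = lp.shape[0]
    idx = labels_to_indices(label)
    if t_frames < min_frames(label):
        return CtcLossResult(np.inf, np.zeros_like(lp))

    ext = _extended(idx)
    s = len(ext)
    # transitions: stay; advance one; skip a blank between distinct bases
    skip_ok = np.zeros(s, dtype=bool)
    skip_ok[2:] = (ext[2:] != BLANK) & (ext[2:] != ext[:-2])

    emit = lp[:, ext]  # (T', S)

    alpha = np.full((t_frames, s), _NEG_INF)
    alpha[0, 0] = emit[0, 0]
    if s > 1:
        alpha[0, 1] = emit[0, 1]
    for t in range(1, t_frames):
        prev = alpha[t - 1]
        acc = prev.copy()
        acc[1:] = np.logaddexp(acc[1:], prev[:-1])
        acc[skip_ok] = np.logaddexp(acc[skip_ok], prev[:-2][skip_ok[2:]])
        alpha[t] = acc + emit[t]

    if s == 1:
        log_z = alpha[-1, 0]
    else:
        log_z = np.logaddexp(alpha[-1, -1], alpha[-1, -2])
    if not np.isfinite(log_z):
        return CtcLossResult(np.inf, np.zeros_like(lp))

    # beta[t, s]: log-prob of completing from state s after frame t
    # (emission at t excluded), so alpha + beta = per-state path mass.
    beta = np.full((t_frames, s), _NEG_INF)
    beta[-1, -1] = 0.0
    if s > 1:
        beta[-1, -2] = 0.0
    for t in range(t_frames - 2, -1, -1):
        nxt = beta[t + 1] + emit[t + 1]
        acc = nxt.copy()
        acc[:-1] = np.logaddexp(acc[:-1], nxt[1:])
        src = np.flatnonzero(skip_ok)
        acc[src - 2] = np.logaddexp(acc[src - 2], nxt[src])
        beta[t] = acc

    # state posteriors, folded per output channel
    post = np.exp(alpha + beta - log_z)  # (T', S)
    grad = np.zeros_like(lp)
    np.add.at(grad.T, ext, post.T)
    return CtcLossResult(float(-log_z), -grad)


def ctc_loss_batch(log_posteriors: np.ndarray, labels: list[str],
                   lengths: np.ndarray | None = None):
    """Batched CTC loss: (B, T, 5) log-posteriors against B labels.

    ``lengths[b]`` gives the number of valid frames of item ``b`` (the
    rest are padding and receive zero gradient).  Returns
    ``(losses, grads)`` with ``losses`` shape (B,) and ``grads`` the
    same shape as the input.  Numerically identical to calling
    :func:`ctc_loss` per item, but the forward/backward recursions run
    vectorized across the batch: frames beyond an item's length are
    forced to emit blank with probability one, which extends every
    complete alignment uniquely and leaves the total path mass — and
    the gradient on real frames — unchanged.
    """
    lp = np.asarray(log_posteriors, dtype=float)
    b, t_max, _ = lp.shape
    if lengths is None:
        lengths = np.full(b, t_max)
    lengths = np.asarray(lengths)
    idxs = [labels_to_indices(lab) for lab in labels]
    feasible = np.array(
        [lengths[i] >= min_frames(labels[i]) for i in range(b)]
    )
    s_max = max(2 * max((len(i) for i in idxs), default=0) + 1, 1)

    ext = np.full((b, s_max), -1, dtype=np.intp)  # -1 = nonexistent state
    n_states = np.empty(b, dtype=np.intp)
    for i, li in enumerate(idxs):
        e = _extended(li)
        ext[i, :len(e)] = e
        n_states[i] = len(e)
    valid = ext >= 0
    skip_ok = np.zeros((b, s_max), dtype=bool)
    skip_ok[:, 2:] = (ext[:, 2:] != BLANK) & (ext[:, 2:] != ext[:, :-2]) & valid[:, 2:]

    # emissions: model log-probs on valid frames, forced blank afterwards
    emit = np.full((b, t_max, s_max), _NEG_INF)
    frame_live = np.arange(t_max)[None, :] < lengths[:, None]  # (B, T)
    safe_ext = np.where(valid, ext, 0)
    gathered = np.take_along_axis(lp, np.broadcast_to(
        safe_ext[:, None, :], (b, t_max, s_max)), axis=2)
    is_blank = (ext == BLANK) & valid
    emit = np.where(frame_live[:, :, None] & valid[:, None, :], gathered, _NEG_INF)
    emit = np.where(~frame_live[:, :, None] & is_blank[:, None, :], 0.0, emit)

    alpha = np.full((b, t_max, s_max), _NEG_INF)
    alpha[:, 0, 0] = emit[:, 0, 0]
    two = n_states > 1
    alpha[two, 0, 1] = emit[two, 0, 1]
    for t in range(1, t_max):
        prev = alpha[:, t - 1]
        acc = prev.copy()
        acc[:, 1:] = np.logaddexp(acc[:, 1:], prev[:, :-1])
        skip_val = np.where(skip_ok[:, 2:], prev[:, :-2], _NEG_INF)
        acc[:, 2:] = np.logaddexp(acc[:, 2:], skip_val)
        alpha[:, t] = acc + emit[:, t]

    rows = np.arange(b)
    log_z = alpha[rows, -1, n_states - 1]
    log_z = np.where(
        n_states > 1,
        np.logaddexp(log_z, alpha[rows, -1, np.maximum(n_states - 2, 0)]),
        log_z,
    )

    beta = np.full((b, t_max, s_max), _NEG_INF)
    beta[rows, -1, n_states - 1] = 0.0
    beta[rows[two], -1, n_states[two] - 2] = 0.0
    for t in range(t_max - 2, -1, -1):
        nxt = beta[:, t + 1] + emit[:, t + 1]
        acc = nxt.copy()
        acc[:, :-1] = np.logaddexp(acc[:, :-1], nxt[:, 1:])
        skip_val = np.where(skip_ok[:, 2:], nxt[:, 2:], _NEG_INF)
        acc[:, :-2] = np.logaddexp(acc[:, :-2], skip_val)
        beta[:, t] = acc

    ok = feasible & np.isfinite(log_z)
    losses = np.where(ok, -log_z, np.inf)
    with np.errstate(invalid="ignore"):
        post = np.exp(alpha + beta - np.where(ok, log_z, 0.0)[:, None, None])
    post[~ok] = 0.0
    post[~valid[:, None, :].repeat(t_max, axis=1)] = 0.0
    grads = np.zeros_like(lp)
    for c in range(5):
        grads[:, :, c] = -(post * ((ext == c) & valid)[:, None, :]).sum(axis=2)
    grads[~frame_live] = 0.0
    return losses, grads


def brute_force_ctc(posteriors: np.ndarray, label: str) -> float:
    """Exact alignment probability by enumerating all 5^T' frame paths.

    Only feasible for very short posteriors (T' ≤ 8); this is the test
    oracle for :func:`ctc_loss`, kept deliberately independent of it.
    """
    p = np.asarray(posteriors, dtype=float)
    t_frames = p.shape[0]
    if t_frames > 8:
        raise ValueError(f"brute force limited to T' <= 8, got {t_frames}")
    total = 0.0
    for path in product(range(5), repeat=t_frames):
        if collapse_path(path) == label:
            total += float(np.prod(p[np.arange(t_frames), path]))
    return total


def collapse_path(path) -> str:
    """Collapse consecutive repeats, then drop blanks."""
    out = []
    prev = None
    for c in path:
        if c != prev and c != BLANK:
            out.append(ALPHABET[c])
        prev = c
    return "".join(out)


def tie_break(frame_probs: np.ndarray) -> int:
    """Deterministic argmax: among equal maxima the lowest channel index
    (A < C < G < T < blank) wins."""
    return int(np.argmax(frame_probs))


def best_path_decode(posteriors: np.ndarray) -> str:
    """Greedy best-path decoding: per-frame argmax, collapse, drop blanks."""
    p = np.asarray(posteriors, dtype=float)
    return collapse_path(np.argmax(p, axis=1))


def beam_search_decode(posteriors: np.ndarray, width: int = 1) -> str:
    """Prefix beam search over collapsed labels (width 1 = greedy).

    Tracks, per surviving prefix, the probability mass of paths ending in
    blank and in the prefix's last base; merges paths mapping to the same
    prefix.  With a handful of beams this can recover labels whose mass is
    split across alignments that greedy decoding misses.
    """
    if width <= 1:
        return best_path_decode(posteriors)
    p = np.asarray(posteriors, dtype=float)
    # prefix -> (prob ending in blank, prob ending in non-blank)
    beams = {"": (1.0, 0.0)}
    for frame in p:
        nxt: dict[str, list[float]] = {}

        def bump(prefix, pb, pnb):
            cur = nxt.setdefault(prefix, [0.0, 0.0])
            cur[0] += pb
            cur[1] += pnb

        for prefix, (pb, pnb) in beams.items():
            bump(prefix, (pb + pnb) * frame[BLANK], 0.0)
            for c in range(4):
                base = ALPHABET[c]
                if prefix and prefix[-1] == base:
                    bump(prefix + base, 0.0, pb * frame[c])  # repeat, via blank
                    bump(prefix, 0.0, pnb * frame[c])        # same run continues
                else:
                    bump(prefix + base, 0.0, (pb + pnb) * frame[c])
        ranked = sorted(nxt.items(), key=lambda kv: -(kv[1][0] + kv[1][1]))
        beams = {k: (v[0], v[1]) for k, v in ranked[:width]}
    return max(beams.items(), key=lambda kv: kv[1][0] + kv[1][1])[0]
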