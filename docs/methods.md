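# Methods

## The problem

Nanopore sequencers report the ionic current through a pore roughly
4000 times per second while a DNA strand translocates at ~450 bases per
second. Each one-base shift of the strand therefore spans about 9
samples on average, with heavy-tailed variability, and the current
level is a function of a short context (5–12 bases) around the pore
head. Base calling inverts this: raw current in, DNA sequence out.
`squigglecall` implements a convolutional base caller in the
QuartzNet/Bonito mold — a 1-D CNN over a signal window, a five-channel
softmax (A, C, G, T, blank) per output frame, and CTC to marginalize
over alignments — built around two factorized convolution designs and
an initialization strategy aimed at fast, stable training.

## Convolution factorizations

A full 1-D convolution maps a `(T, Cin)` tensor to `(T, Cout)` with
`Cout·D·Cin` weights and `T·Cout·D·Cin` multiplications. The standard
separable factorization (depthwise of depth D, then pointwise) cuts
this to `T·(D·Cin + Cout·Cin)`. The k-blueprint-separable convolution
factorizes differently: a *fat-pointwise* convolution — an ordinary
convolution of small odd depth `k` mixing channels — followed by a
*k-dilated depthwise* convolution of depth `D/k`. The receptive field
stays `D`, the depthwise kernel shrinks by a factor of `k`, and the
parameter count (`Cout·k·Cin + (D/k)·Cout`) grows roughly `k`-fold over
the separable form, increasing expressive power at similar depthwise
cost. `k = 1` recovers the ordinary blueprint-separable convolution
(pointwise before depthwise). For `D = 15`, `k = 3`, `C = 128` the
weight count is 49 792 versus 18 304 separable — a ratio of 2.72.

Padding is centred throughout: the fat-pointwise stage pads `⌊k/2⌋`
zeros per side, the dilated depthwise `⌊(D/k)/2⌋·k`, so every stride-1
operator preserves length and output frame `t` is centred on input
frame `t`. When `D/k` is even the receptive field is asymmetric; the
constructor warns but proceeds. `D` not divisible by `k` is rejected.

## The compressed residual block

The residual block follows the QuartzNet B-type design — a main branch
of repeated convolution sub-blocks and a pointwise+batch-norm skip,
summed and passed through Swish — with the first and last separable
convolutions replaced by a depth-to-space compression pair: a strided
convolution with depth = stride = `x` turns `(T, C)` into
`(T/x, C·y)`, and a strided transposed convolution (depth = stride, so
writes never overlap) restores `(T, C)`. In between sit `R − 2`
k-blueprint-separable sub-blocks at the compressed resolution and one
plain depthwise operation before decompression. With ratio `x:y = 3:2`
the intermediate tensors shrink by a third while pointwise work per
original sample grows by `y²/x = 4/3`; every pointwise operation in the
compressed domain mixes `x` original timesteps, enlarging the effective
receptive field. The block's shape contract is identical to the
uncompressed block — a drop-in replacement.

Choices the block-level design left open, and what this package does:

* Each inner sub-block is k-separable conv + batch norm + Swish.
* The pre-decompression depthwise operation has depth `D/x` rounded to
  the nearest odd ≥ 1 (5 for `D = 15`, `x = 3`) and is followed by a
  batch norm without activation, mirroring the convention that the last
  main-branch copy omits its activation.
* The decompression output passes through its own batch norm before the
  branch sum, symmetric with the skip branch.
* The skip operates at full resolution and is summed after
  decompression.
* If `T` is not a multiple of `x`, the compression right-pads with
  zeros and the block trims after decompression, preserving length.

## Identity initialization

All k-separable convolutions inside compressed main branches are
initialized to near-identity: depthwise kernels get a centred delta
(`W[d, j] = 1` iff `d = ⌊(D/k)/2⌋`), fat-pointwise kernels a centred
identity channel map plus uniform noise `U(−ε, ε)` with `ε = 0.02` by
default, and zero biases. The pre-decompression depthwise operation is
also set to a centred delta. Everything else — compression,
decompression, skip, C-blocks, decoder — uses Glorot-uniform weights
with bound `sqrt(6/(Cin + Cout))` and zero biases. Initialization is a
deterministic function of the seed.

The motivating intuition: base calling decomposes into segmenting the
signal into per-base events (hard — dwell lengths are highly variable)
and classifying the base given a segment (easy — even a one-feature
logistic regression separates purines from pyrimidines on correctly
segmented events, which `experiment_purine_probe` reproduces). Starting
the deep main branches at the identity lets the network learn the easy
mapping first without having to unlearn spurious long-range structure
from random initial weights. `experiment_boundary_input`, which feeds
ground-truth event boundaries as an extra input channel, shows the same
thing from the other side: with segmentation given away, training
reaches a fixed accuracy in far fewer steps. That arm is diagnostic
only — no real base caller can see ground-truth boundaries.

A note on "identity": at `ε = 0` the *linear + batch-norm* path of each
sub-block is an exact identity map (the tests set the batch-norm
epsilon to zero for exactness; the default 1e-5 introduces a ~5e-6
relative contraction). The Swish activation is not the identity
anywhere except asymptotically, so exact-identity statements here and
in the tests always refer to the pre-activation path, and the
whole-main-branch identity check disables the inner activations.

## Network, CTC and decoding

A model is an ordered block list from a YAML config: a strided C-type
head (full convolution, stride 3 — one output frame per three signal
samples, matching ~3 frames per base), residual blocks, one or two
C-type tail blocks, and a decoder (pointwise to 5 channels + row-wise
softmax). The channel chain is validated at construction; the decoder
must emit exactly 5 channels in the fixed order A, C, G, T, blank.

The CTC loss is the standard forward recursion over the blank-augmented
state sequence, entirely in log space; its gradient comes from the
forward/backward state posteriors and is finite-difference-verified. An
infeasible label (longer than the frames can carry, counting the blank
required between repeated bases) yields an infinite loss rather than an
exception. A brute-force path enumerator (all `5^T'` paths, `T' ≤ 8`)
is kept as the independent oracle. Decoding is greedy best-path —
per-frame argmax with ties resolved to the lowest channel index,
collapse repeats, drop blanks — with an optional prefix beam search
(`width > 1`) that merges path mass per collapsed prefix.

Long signals are base called in overlapping windows whose starts sit on
the network's shift-equivariance grid (total stride × every
compression factor; 9 for the shipped configs). Each window keeps only
its interior frames, so interior output is identical to an unchunked
run and the stitched posterior has exactly `⌈T/stride⌉` rows.

There is no automatic-differentiation dependency: every layer is a
forward/backward pair in NumPy, verified against central finite
differences layer-by-layer and end-to-end through the full network and
CTC loss.

## The squiggle simulator

The simulator provides ground truth the real world cannot: exact
sequences, dwell times and event boundaries. Its defaults encode the
stated signal model:

* **Dwell**: `1 + NegativeBinomial`, mean 4000/450 ≈ 8.9 samples per
  base, variance ≈ 3 × mean (CV ≈ 0.58 — "large variance"), minimum 1.
* **Level**: an additive table over a 6-base context window — each
  position contributes a per-base level, strongest at the centre
  (A = 1.0, G = 0.6, C = −0.6, T = −1.0, so purines and pyrimidines
  separate by far more than one noise SD) and decaying as `0.3/(1+d)`
  with distance — plus a small seeded interaction (±0.1) between the
  central base and each neighbour, so that distinct contexts can
  produce near-identical levels. An additive table was chosen over a
  `4^c` lookup for desk-scale memory while remaining genuinely
  context-dependent.
* **Noise**: i.i.d. Gaussian, SD 0.25 in level units. No quantitative
  noise figure is available for the modelled chemistry; 0.25 is a
  declared stand-in and is recorded in dataset headers.

Signals are normalized per read by median/MAD (`(x − median)/(1.4826 ·
MAD)`), identically at training and inference time; the constant
1.4826 makes the scale estimate consistent with the SD under
normality. One consequence of robust per-read normalization worth
knowing: with a small discrete set of levels the median snaps onto one
of them, so normalized level positions shift slightly from read to
read. The purine probe therefore uses raw event means, which the
simulator emits on a common scale.

What the simulator does **not** model: real R9.4.1 pore chemistry and
its measured 6-mer tables, homopolymer-specific dwell behaviour,
current drift, stalls, adapter/barcode signal, or per-read scale and
offset variation. Accuracy numbers on this data characterize the
architecture and training machinery, not expected performance on real
reads.

## Training at desk scale

Training cuts fixed-length chunks (default 432 samples ≈ 48 bases)
starting at random event boundaries, zero-padded past the spanned
events; the CTC loss runs on each chunk's valid frames. The optimizer
is Adam (lr 2e-3, batch 16) with a short linear warmup and a cosine
decay to 5% of the peak rate — no training schedule is prescribed by
the architecture itself; these are this package's desk-scale choices,
all overridable via `TrainConfig`. Training computation runs in
float32 (roughly halving step time); the functional reference operators
and all oracle tests remain float64. Batch order, chunk sampling and
initialization are deterministic given the config seed. The held-out
split is by CRC32 hash of the read id (~20%).

The shipped `default` config (48 channels, three compressed residual
blocks with `D = 15`, `k = 3`, `R = 4`, ratio 3:2, ~274k parameters)
is sized so that a full simulate → train → basecall → evaluate cycle
on a few hundred reads of 200–500 bases completes in minutes on one
CPU core. The `large` config (64 channels, five blocks, `R = 5`, ~1.0M
parameters) is the closer analogue of a production base caller and
trains proportionally slower; the `tiny` config exists for controlled
experiments (initialization ablation, boundary-input probe) where many
short training runs are needed.

"Mapped %" in accuracy reports is reinterpreted for synthetic data as
the fraction of reads with a nonempty decoded call: there is no
aligner in this pipeline, and the read-accuracy denominator is the
call length, so empty calls are excluded rather than scored.

## Numerical details and edge cases

* Posterior rows must sum to 1 within 1e-6 (validated on
  construction); log-softmax + exp agrees with softmax to ~1e-9.
* CTC runs in log space with `logaddexp`; feasible for frame counts
  up to at least 1e5 without underflow.
* Greedy-decode ties go to the lowest channel index (A first),
  deterministically.
* Degenerate inputs fail loudly: constant signals (MAD = 0), too-short
  signals (shorter than the receptive field), inconsistent channel
  chains, even full-convolution depths, `D` not divisible by `k`.
* Weight archives are `.npz` files of named float64 (or float32, if
  the model was cast) tensors plus a JSON manifest; save → load →
  forward is bit-exact.

## Known limitations

* CTC training on this simulator is budget-limited, not
  capacity-limited: at the default desk-scale budgets the held-out
  median accuracy the acceptance script computes sits around 0.7 and
  climbs only slowly with more steps, while the diagnostic arm that is
  handed ground-truth event boundaries converges far higher in a
  fraction of the steps. Learning the segmentation is the slow part;
  reaching the architecture's ceiling takes substantially more
  optimization than a single-core NumPy training loop delivers in
  minutes.
* Greedy decoding underestimates what the posterior knows when path
  mass is split across alignments; the beam decoder recovers some of
  it but no language-model-style rescoring is attempted.
* The training loop holds the whole (small) dataset in memory and
  targets a single CPU core; there is no data-parallelism.
* Quantization and hardware-accelerator deployment are out of scope;
  everything runs in floating point.
* Accuracies reported anywhere in this repository are on synthetic
  reads and are not comparable to published real-data base-calling
  accuracies.
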