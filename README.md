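# squigglecall

A convolutional nanopore base caller — raw current signal in, DNA
sequence out — built from scratch around three ideas for making
CNN-CTC base calling cheap:

* **k-blueprint-separable convolutions**: a full 1-D convolution of
  depth *D* is factorized into a "fat" pointwise convolution of small
  odd depth *k* (channel mixing over a k-wide window) followed by a
  *k*-dilated depthwise convolution of depth *D/k*. The receptive
  field stays *D*, the depthwise kernel shrinks k-fold, and the
  parameter count `Cout·k·Cin + (D/k)·Cout` is roughly *k* times the
  separable count — more expressive power per depthwise memory access.
  `k = 1` recovers the ordinary blueprint-separable convolution.
* **Residual blocks with depth-to-space compression**: a strided
  convolution with depth = stride = *x* turns `(T, C)` activations into
  `(T/x, C·y)` before the block's inner convolutions, and a strided
  transposed convolution restores `(T, C)` at the end. With ratio
  `x:y = 3:2` the block saves memory while every inner pointwise
  operation mixes *x* original timesteps.
* **Identity initialization**: the k-separable convolutions inside the
  compressed main branches start as (near-)identity maps — centred
  delta depthwise kernels, centred identity-plus-`U(−ε, ε)`
  fat-pointwise kernels — instead of Glorot noise. Base calling splits
  into segmenting the signal into per-base events (hard) and
  classifying the base given a segment (easy); starting at the
  identity lets the network learn the easy part first.

The network is the familiar CNN-CTC topology: a stride-3 convolutional
head, residual blocks, and a decoder emitting per-frame probabilities
over {A, C, G, T, blank}; training uses the CTC loss and decoding is
greedy best-path (optional prefix beam search). All layers, their
gradients and the optimizer are implemented directly in NumPy and
verified against finite differences; there is no deep-learning
framework dependency.

Because real nanopore reads need external data and long training, the
package ships a **squiggle simulator** as a first-class component: ~9
samples per base with heavy-tailed dwell times (4 kHz sampling, ~450
bases/s translocation), signal levels set by a 6-base sequence context,
Gaussian readout noise, and full ground truth (sequence, dwells, event
boundaries) for every read. All training, evaluation and experiments in
this repository run on simulated data; accuracies are not comparable to
real-data base-calling numbers (see `docs/methods.md`).

## Who is this for

People studying base-caller architectures — convolution factorizations,
compression, initialization, CTC training dynamics — who want a small,
fully inspectable, dependency-light implementation where every operator
is testable against its defining formula, plus a simulator that makes
controlled experiments (e.g. "what if the network knew the event
boundaries?") possible at desk scale.

## Worked example

```python
from squigglecall import PoreModel, ModelConfig
from squigglecall.squiggle_sim import simulate_dataset
from squigglecall.train_eval import TrainConfig, train, evaluate, split_reads

reads = simulate_dataset(200, PoreModel(), min_len=150, max_len=250, seed=7)
train_reads, held_out = split_reads(reads)

cfg = TrainConfig(steps=600, seed=0, batch_size=8)
result = train(train_reads, cfg, config=ModelConfig.named("tiny"))
print(f"final training loss: {result.loss_curve[-1]:.2f}")

report = evaluate(result.model, held_out, window=2997)
print(f"held-out reads: {report.n_reads}")
print(f"mapped fraction: {report.mapped_fraction:.2f}")
print(f"median read accuracy: {report.median:.3f}")
```

prints (about half a minute on one core):

```
final training loss: 47.60
held-out reads: 33
mapped fraction: 1.00
median read accuracy: 0.540
```

The loss is the mean CTC negative log-likelihood per training chunk
(~48 bases here), "mapped" is the fraction of held-out reads with a
nonempty decoded call, and read accuracy is
`1 − editDistance(call, reference) / |call|`, reported as the median
over reads. 0.54 after 600 steps on the 32k-parameter `tiny` model is
an early-training snapshot; the shipped `default` model (274k
parameters) trained for a few thousand steps reaches ~0.7 median on
this simulator (the acceptance script below measures this exactly).

The same pipeline is available from the shell:

```sh
squigglecall simulate --n-reads 200 --seed 7 --out-prefix data/ds
squigglecall train --signals data/ds.signals.tsv --fasta data/ds.fasta \
    --meta data/ds.meta.json --steps 600 --out model.npz
squigglecall basecall --signals data/ds.signals.tsv --weights model.npz \
    --out calls.fasta
squigglecall eval --calls calls.fasta --references data/ds.fasta
```

Raw signals travel as a plain TSV (`read_id TAB comma-separated
samples`), calls as FASTA/FASTQ, reports as JSON; model configs are
YAML (see `src/squigglecall/configs/`).

## Repository layout

| Path | Contents |
| --- | --- |
| `src/squigglecall/conv_ops.py` | the 1-D operators as pure functions of their defining sums |
| `src/squigglecall/nn.py` | trainable layers with hand-derived gradients |
| `src/squigglecall/blocks.py` | C-type, Bonito-style and compressed residual blocks; identity init |
| `src/squigglecall/network.py` | config-driven model assembly, inference, chunking, serialization |
| `src/squigglecall/ctc.py` | CTC loss (+ batched variant), greedy/beam decoding, brute-force oracle |
| `src/squigglecall/squiggle_sim.py` | the synthetic squiggle generator |
| `src/squigglecall/train_eval.py` | training loop, read accuracy, the three experiments |
| `src/squigglecall/io_cli.py` | file formats and the `squigglecall` CLI |
| `docs/methods.md` | model, assumptions, parameter choices, limitations |
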