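# Minimal architecture for fast controlled experiments (ablations,
# boundary-input probe); same topology, far fewer channels.
in_channels: 1
blocks:
  - {type: c, cout: 24, depth: 9, stride: 3, conv_kind: full}
  - {type: residual_compressed, c: 24, depth: 9, r: 3, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 24, depth: 9, r: 3, k: 3, x: 3, y: 2}
  - {type: c, cout: 32, depth: 9, conv_kind: separable}
  - {type: decoder, cout: 5}
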