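# Wider/deeper stand-in closer to a production base caller: five
# compressed residual blocks of 64 channels with R = 5.
in_channels: 1
blocks:
  - {type: c, cout: 64, depth: 9, stride: 3, conv_kind: full}
  - {type: residual_compressed, c: 64, depth: 15, r: 5, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 64, depth: 15, r: 5, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 64, depth: 15, r: 5, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 64, depth: 15, r: 5, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 64, depth: 15, r: 5, k: 3, x: 3, y: 2}
  - {type: c, cout: 96, depth: 15, conv_kind: separable}
  - {type: c, cout: 64, depth: 9, conv_kind: separable}
  - {type: decoder, cout: 5}
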