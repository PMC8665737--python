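# Desk-trainable base-caller: stride-3 head, three compressed residual
# blocks (k = 3, compression 3:2), separable tail, 5-channel decoder.
in_channels: 1
blocks:
  - {type: c, cout: 48, depth: 9, stride: 3, conv_kind: full}
  - {type: residual_compressed, c: 48, depth: 15, r: 4, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 48, depth: 15, r: 4, k: 3, x: 3, y: 2}
  - {type: residual_compressed, c: 48, depth: 15, r: 4, k: 3, x: 3, y: 2}
  - {type: c, cout: 64, depth: 15, conv_kind: separable}
  - {type: c, cout: 64, depth: 1, conv_kind: full}
  - {type: decoder, cout: 5}
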