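# Architecture variants: per-stage channels/depths, window sizes per branch,
# per-head query dimension and MLP expansion.  "tiny" is a reduced variant for
# CPU-scale tests only.
S:
  channels: [96, 192, 384, 768]
  depths: [2, 2, 2, 2]
  window_sizes: [7, 9, 11]
  head_dim: 32
  mlp_ratio: 4.0
B:
  channels: [96, 192, 384, 768]
  depths: [2, 2, 6, 2]
  window_sizes: [7, 9, 11]
  head_dim: 32
  mlp_ratio: 4.0
L:
  channels: [96, 192, 384, 768]
  depths: [2, 2, 18, 2]
  window_sizes: [7, 9, 11]
  head_dim: 32
  mlp_ratio: 4.0
tiny:
  channels: [16, 32, 64, 128]
  depths: [2, 2, 2, 2]
  window_sizes: [3, 5]
  head_dim: 8
  mlp_ratio: 2.0
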