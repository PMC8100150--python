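# Three separated sources in the cuboid volume: constant field vs
# ten-layer gradient-field multiple Z scan (coarse grid by default).
mode: gradient_scan
grid:
  kind: cuboid
  extent: [6.0, 6.0, 5.0]
  spacing: 0.5
source:
  centers: [[1.0, 1.0, 2.0], [3.0, 3.0, 3.0], [5.0, 5.0, 4.0]]
  sigma: 0.1
  combine: true
plane:
  extent: [8.0, 8.0]
  interval: 0.5
  z: 6.0
n_layers: 10
bias: 0.5
threshold: 0.15
solver:
  tol: 1.0e-8
  max_iter: 30000
full_overrides:
  grid:
    spacing: 0.1
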