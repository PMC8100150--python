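# Constant field vs gradient-field multiple Z scan, three source depths,
# on the ellipsoidal stand-in (sources on the stand-in's vertical axis:
# shallow / middle / deep).
mode: gradient_scan
grid:
  kind: ellipsoid
  bbox: [5.0, 4.0, 1.5]
  spacing: 0.25
source:
  centers: [[2.5, 2.0, 1.25], [2.5, 2.0, 0.75], [2.5, 2.0, 0.25]]
  sigma: 0.1
  combine: false
plane:
  extent: [6.0, 5.0]
  interval: 0.5
  z: 2.5
n_layers: 5
bias: 0.5
threshold: 0.3
solver:
  tol: 1.0e-8
  max_iter: 30000
full_overrides:
  grid:
    spacing: 0.1
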