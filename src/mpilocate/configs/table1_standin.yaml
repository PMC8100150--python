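# Constant-field plane sweep on the ellipsoidal stand-in volume.
# Coarse grid by default; full_overrides restores fine spacing/interval.
mode: constant_field
grid:
  kind: ellipsoid
  bbox: [5.0, 4.0, 1.5]
  spacing: 0.25
source:
  centers: [[1.5, 1.8, 1.0]]
  sigma: 0.1
plane:
  extent: [6.0, 5.0]
  interval: 0.5
  z_list: [2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0]
bias: 0.5
solver:
  max_iter: 30000
full_overrides:
  grid:
    spacing: 0.1
  plane:
    interval: 0.1
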