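# 2D reference run: 100 CTCs diffusing with no flow above the vessel wall.
# Slice profiles at y = 0 (wall), 150, 300 and the per-slice peak series.
# The cells sit in a near-wall layer (y <= 20); see docs/methods.md for how
# the layer height is constrained by the late-time wall dominance and the
# T ~ 3 regime change of the reference results.
mode: no_flow_2d
u: 0.0
normalization: as_printed
seed: 2012
sources:
  kind: recipe
  count: 100
  strength: 1.0
  alpha: 1.5
  box:
    x: [0.0, 600.0]
    y: [0.0, 20.0]
times: [1.0, 5.0, 15.0, 500.0]
peak_times:
  start: 1.0
  stop: 500.0
  num: 48
  spacing: log
slices:
  - {axis: y, offset: 0.0}
  - {axis: y, offset: 150.0}
  - {axis: y, offset: 300.0}
window:
  x: [0.0, 600.0]
  y: [0.0, 600.0]
resolution: 256
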