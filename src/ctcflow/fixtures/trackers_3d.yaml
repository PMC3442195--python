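# 3D tracker run: 100 random CTCs in constant flow plus passive gradient
# trackers (200 high-seeking "red", 200 low-seeking "blue"). Frame times
# follow the five-panel tracker-evolution sequence.
mode: constant_flow_3d
u: 1.0
normalization: as_printed
seed: 2012
sources:
  kind: recipe
  count: 100
  strength: 1.0
  alpha: 1.5
  box:
    x: [0.0, 600.0]
    y: [0.0, 600.0]
    z: [0.0, 90.0]
times: [8.0, 46.0, 99.0, 167.0, 220.0]
slices:
  - {axis: z, offset: 0.0}
window:
  x: [0.0, 900.0]
  y: [0.0, 600.0]
  z: [0.0, 90.0]
resolution: 128
trackers:
  count_high: 200
  count_low: 200
  box:
    x: [0.0, 600.0]
    y: [0.0, 600.0]
    z: [0.0, 90.0]
  eps: 2.0
  cadence: 0.5
  t0: 1.0
  t1: 220.0
  seed: 2013
  frame_times: [8.0, 46.0, 99.0, 167.0, 220.0]
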