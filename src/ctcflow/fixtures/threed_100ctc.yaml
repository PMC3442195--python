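# 3D reference run: 100 randomly placed CTCs in constant flow (u = 1),
# same diffusion coefficient, slices and times as the four-CTC run so the
# field levels can be compared (expected roughly linear in CTC count).
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
times: [1.0, 10.0, 40.0, 75.0]
slices:
  - {axis: z, offset: 0.0}
  - {axis: z, offset: 45.0}
  - {axis: z, offset: 90.0}
window:
  x: [0.0, 600.0]
  y: [0.0, 600.0]
  z: [0.0, 90.0]
resolution: 256
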