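dims: [40, 24, 24]
voxel_sizes: [1.0, 1.0, 1.0]
seed: 7
bundles:
  - kind: line
    start: [4.5, 12.5, 12.5]
    end: [35.5, 12.5, 12.5]
    n_streamlines: 20
    spacing: 1.0
    jitter_sd: 0.4
rois:
  gtv:
    shape: sphere
    center: [6.5, 12.5, 12.5]
    radius: 2.5
    role: GTV
  brain:
    shape: box
    bounds: [[0.0, 40.0], [0.0, 24.0], [0.0, 24.0]]
    role: brain
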