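# Desk-scale configuration used by the README walk-through: everything is
# shrunk from the production geometry (160/188 cubes, 64/36 windows) to run
# on a laptop CPU in seconds while keeping all ratios intact.
seed: 5
phantom:
  cube_edge: 32
  pad: 8
  n_tubes: 4
sampler:
  input_size: 32
  margin: 8
  oversample_p: 0.3
  samples_per_cube: 16
network:
  depth: 3
  base_filters: 4
  input_size: 32
  margin: 8
train:
  epochs: 2
  batch_size: 6
  learning_rate: 0.01
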