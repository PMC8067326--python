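# Two granules (first and fourth quadrant) in a disk of radius 8.
[domain]
shape = "disk"
size_params = [8.0]
h_target = 0.15

[[granules]]
center = [2.5, 2.5]
radius = 1.0
pinned_value = 1.0

[[granules]]
center = [2.5, -2.5]
radius = 1.0
pinned_value = 1.0

[solver]
gamma = 1.0
dt = 0.001
n_steps = 900
seed = 0

[output]
directory = "out_disk_r8_two_granules"
record_every = 100
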