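# One calcium phosphate granule (first quadrant) in a disk of radius 5.
# Granule boundary pins the order parameter to C = +1 (matrix).
[domain]
shape = "disk"
size_params = [5.0]
h_target = 0.15

[[granules]]
center = [2.5, 2.5]
radius = 1.0
pinned_value = 1.0

[solver]
gamma = 1.0
dt = 0.005
n_steps = 1400
seed = 0

[output]
directory = "out_disk_r5_granule"
record_every = 100
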