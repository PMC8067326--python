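# 3D: sphere of radius 5 with a single granule. Coarser h than in 2D keeps
# the tetrahedral problem at desk scale.
[domain]
shape = "sphere"
size_params = [5.0]
h_target = 0.35

[[granules]]
center = [2.5, 0.0, 0.0]
radius = 1.0
pinned_value = 1.0

[solver]
gamma = 1.0
dt = 0.001
n_steps = 1500
seed = 0

[output]
directory = "out_sphere_r5_granule"
record_every = 250
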