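# 3D ellipsoid with full axes 10 x 8 x 8.
[domain]
shape = "ellipsoid"
size_params = [10.0, 8.0, 8.0]
h_target = 0.35

[solver]
gamma = 1.0
dt = 0.005
n_steps = 60
seed = 0

[output]
directory = "out_ellipsoid_10x8x8"
record_every = 20
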