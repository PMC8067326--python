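# Ellipse with full major axis 10 and full minor axis 8 (semi-axes 5 and 4).
[domain]
shape = "ellipse"
size_params = [10.0, 8.0]
h_target = 0.15

[solver]
gamma = 1.0
dt = 0.005
n_steps = 1000
seed = 0

[output]
directory = "out_ellipse_10x8"
record_every = 200
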