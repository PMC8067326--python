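# Calcium-free protocol on the larger disk of radius 5 (thinner cristae).
[domain]
shape = "disk"
size_params = [5.0]
h_target = 0.15

[solver]
gamma = 1.0
dt = 0.001
n_steps = 2250
seed = 0

[output]
directory = "out_disk_r5"
record_every = 250
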