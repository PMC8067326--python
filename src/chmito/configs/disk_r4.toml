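# Calcium-free protocol: disk of radius 4, gamma = 1, dt = 0.001,
# snapshots every 250 steps up to step 2250.
[domain]
shape = "disk"
size_params = [4.0]
h_target = 0.15

[solver]
gamma = 1.0
dt = 0.001
n_steps = 2250
seed = 0

[output]
directory = "out_disk_r4"
record_every = 250
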