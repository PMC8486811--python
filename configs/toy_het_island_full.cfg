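# Heterochromatin island over beads 901-940 (four active TUs embedded).
[fibre]
spec = toy-het-island

[run]
n_runs = 800
base_seed = 1

[tf]
n_tf = 20
switching_mode = toy

[confinement]
kind = sphere
radius = 25.0

[durations]
warmup_pushoff = 300
warmup_equil = 1000
production = 100000
sample_interval = 100

[output]
out_dir = out/toy_het_island
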