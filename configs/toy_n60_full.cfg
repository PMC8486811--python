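# High TF copy number (n = 60 active on average): network simplification.
[fibre]
spec = toy-wt

[run]
n_runs = 800
base_seed = 1

[tf]
n_tf = 120
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
out_dir = out/toy_n60
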