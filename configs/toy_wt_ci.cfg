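# Wild-type toy chain, CI-scale variant (10 runs x 5e3 tau_B).
[fibre]
spec = toy-wt

[run]
n_runs = 10
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
production = 5000
sample_interval = 100

[output]
out_dir = out/toy_wt_ci
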