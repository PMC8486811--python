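# Wild-type toy chain, full (cluster-scale) protocol:
# 1000 simulations x 1e5 tau_B, 20 switchable TFs (half active on average).
[fibre]
spec = toy-wt

[run]
n_runs = 1000
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
out_dir = out/toy_wt_full
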