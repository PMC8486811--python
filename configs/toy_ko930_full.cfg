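# Knockout of TU bead 930 (eQTL/SNP model); compare against toy-wt runs.
[fibre]
spec = toy-ko-930

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
out_dir = out/toy_ko930
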