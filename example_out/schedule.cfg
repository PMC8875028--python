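total_mcs = 400000
equil_mcs = 280000
measure_every = 1200
n_measurements = 100
n_runs = 4
base_seed = 1
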