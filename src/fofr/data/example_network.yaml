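# 50-cell heterogeneous ensemble; VIP exchange switched on after 20 h
n_cells: 50
rate_jitter: 0.2
initial_jitter: 0.2
seed: 1
coupling_schedule: [[0.0, 0.0], [72000.0, 0.5]]
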