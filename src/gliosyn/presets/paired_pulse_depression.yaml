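# Paired-pulse depression: single pair, ISI 100 ms, first-pulse RR = U0 = 0.7
seed: 0
synapse: {omega_d: 10.0, omega_f: 100.0, u0_star: 0.7}
stimulus: {kind: pairs, isi_s: 0.1, pair_rate_hz: 1.0, n_pairs: 1}
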