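# Paired-pulse protocol (ISI 100 ms at 1 Hz) on a depressing synapse with a
# release-decreasing astrocyte; GRE at t = 1 s flips mean PPR above 1
seed: 1
synapse: {omega_d: 2.0, omega_f: 3.3, u0_star: 0.5}
astro: {alpha: 0.0, omega_g_per_min: 1.0}
stimulus: {kind: pairs, isi_s: 0.1, pair_rate_hz: 1.0, n_pairs: 60}
gre: {kind: times, times: [1.0]}
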