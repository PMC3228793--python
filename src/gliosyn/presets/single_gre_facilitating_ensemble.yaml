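# Release-increasing astrocyte (alpha=1) on a facilitating synapse
seed: 1
synapse: {omega_d: 2.0, omega_f: 2.0, u0_star: 0.15}
astro: {alpha: 1.0, omega_g_per_min: 1.0}
gre: {kind: times, times: [10.0]}
ensemble: {n_trials: 100, rate_hz: 1.5, duration_s: 60.0}
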