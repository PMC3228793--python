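# Release-decreasing astrocyte (alpha=0) on a depressing synapse:
# single gliotransmitter release event at t=10 s, 100 Poisson trials at 1.5 Hz
seed: 1
synapse: {omega_d: 2.0, omega_f: 3.3, u0_star: 0.5}
astro: {alpha: 0.0, omega_g_per_min: 1.0}
gre: {kind: times, times: [10.0]}
ensemble: {n_trials: 100, rate_hz: 1.5, duration_s: 60.0}
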