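# Depressing synapse frequency-response (plateau RR = U0 = 0.5)
seed: 0
synapse: {omega_d: 2.0, omega_f: 3.3, u0_star: 0.5}
meanfield: {f_start_hz: 1.0e-3, f_stop_hz: 100.0, n_points: 400, log: true}
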