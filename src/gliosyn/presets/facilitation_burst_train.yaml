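# Facilitation-then-depression: 200 Hz periodic drive, peak RR = 0.2 at spike 3
seed: 0
synapse: {omega_d: 10.0, omega_f: 1.25, u0_star: 0.1}
stimulus: {kind: periodic, freq_hz: 200.0, n_spikes: 15}
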