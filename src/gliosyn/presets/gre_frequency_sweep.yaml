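# GRE-frequency sweep for a release-decreasing astrocyte on a depressing
# synapse: the PPF/PPD ratio grows with f_C
seed: 1
synapse: {omega_d: 2.0, omega_f: 3.3, u0_star: 0.5}
astro: {alpha: 0.0, omega_g_per_min: 1.0}
ensemble:
  n_trials: 100
  rate_hz: 1.5
  duration_s: 120.0
  fc_values_hz: [0.0, 0.008333333333, 0.016666666667, 0.033333333333, 0.083333333333]
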