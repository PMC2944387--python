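{
  "cell_type": "tc_full",
  "comment": "Full thalamocortical relay cell: leak + Na + K (Rinzel reductions m=m_inf, n=1-h) + T-type Ca. Silent at rest, tonic firing under depolarization, rebound bursting after release from hyperpolarization.",
  "C_m": 1.0,
  "g_L": 0.05,
  "E_L": -70.0,
  "g_Na": 3.0,
  "E_Na": 50.0,
  "g_K": 5.0,
  "E_K": -90.0,
  "g_T": 5.0,
  "E_T": 0.0,
  "m_theta": -37.0,
  "m_sigma": 7.0,
  "h_theta": -41.0,
  "h_sigma": -4.0,
  "h_a_scale": 0.128,
  "h_a_theta": -46.0,
  "h_a_sigma": 18.0,
  "h_b_scale": 4.0,
  "h_b_theta": -23.0,
  "h_b_sigma": 5.0,
  "p_theta": -60.0,
  "p_sigma": 6.2,
  "r_theta": -84.0,
  "r_sigma": -4.0,
  "tau_r_base": 28.0,
  "tau_r_scale": 1.0,
  "tau_r_theta": -25.0,
  "tau_r_sigma": 10.5,
  "phi_r": 1.0
}
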