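{
  "cell_type": "stn",
  "comment": "Subthalamic nucleus cell: leak + Na + K + low-threshold T-type Ca + high-threshold Ca + Ca-activated AHP K current. Spontaneously active, high-frequency firing when depolarized, modest rebound.",
  "C_m": 1.0,
  "g_L": 2.25,
  "E_L": -60.0,
  "g_Na": 37.5,
  "E_Na": 55.0,
  "g_K": 45.0,
  "E_K": -80.0,
  "g_T": 0.5,
  "g_Ca": 0.5,
  "E_Ca": 140.0,
  "g_AHP": 9.0,
  "ahp_k1": 15.0,
  "ca_eps": 5e-05,
  "ca_k": 22.5,
  "m_theta": -30.0,
  "m_sigma": 15.0,
  "h_theta": -39.0,
  "h_sigma": -3.1,
  "n_theta": -32.0,
  "n_sigma": 8.0,
  "r_theta": -67.0,
  "r_sigma": -2.0,
  "a_theta": -63.0,
  "a_sigma": 7.8,
  "s_theta": -39.0,
  "s_sigma": 8.0,
  "tau_h0": 1.0,
  "tau_h1": 500.0,
  "tau_h_theta": -57.0,
  "tau_h_sigma": -3.0,
  "tau_n0": 1.0,
  "tau_n1": 100.0,
  "tau_n_theta": -80.0,
  "tau_n_sigma": -26.0,
  "tau_r0": 40.0,
  "tau_r1": 17.5,
  "tau_r_theta": -68.0,
  "tau_r_sigma": -2.2,
  "phi_h": 0.75,
  "phi_n": 0.75,
  "phi_r": 0.2
}
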