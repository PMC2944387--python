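{
  "cell_type": "gpe",
  "comment": "External globus pallidus cell: continuous firing under baseline striatal drive; slows then cluster-fires under increasing inhibition; bursts terminated by the Ca-activated AHP current.",
  "C_m": 1.0,
  "g_L": 0.1,
  "E_L": -55.0,
  "g_Na": 120.0,
  "E_Na": 55.0,
  "g_K": 30.0,
  "E_K": -80.0,
  "g_T": 0.5,
  "g_Ca": 0.15,
  "E_Ca": 120.0,
  "g_AHP": 30.0,
  "ahp_k1": 30.0,
  "ca_eps": 0.0004,
  "ca_k": 15.0,
  "m_theta": -37.0,
  "m_sigma": 10.0,
  "h_theta": -58.0,
  "h_sigma": -12.0,
  "n_theta": -50.0,
  "n_sigma": 14.0,
  "r_theta": -70.0,
  "r_sigma": -2.0,
  "a_theta": -57.0,
  "a_sigma": 2.0,
  "s_theta": -35.0,
  "s_sigma": 2.0,
  "tau_h0": 0.05,
  "tau_h1": 0.27,
  "tau_h_theta": -40.0,
  "tau_h_sigma": -12.0,
  "tau_n0": 0.05,
  "tau_n1": 0.27,
  "tau_n_theta": -40.0,
  "tau_n_sigma": -12.0,
  "tau_r0": 30.0,
  "tau_r1": 0.0,
  "tau_r_theta": -65.0,
  "tau_r_sigma": -2.0,
  "phi_h": 0.05,
  "phi_n": 0.05,
  "phi_r": 1.0
}
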