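{
  "cell_type": "tc_reduced",
  "comment": "Two-variable thalamocortical relay cell: voltage v and T-current availability w. No fast Na/K spikes; relay events are slow T-current excitability events. GPi inhibition enters as a conductance-based synaptic current g_GiTh * s_Gi * (v - E_GiTh).",
  "C_m": 1.0,
  "g_L": 0.05,
  "E_L": -70.0,
  "g_T": 5.0,
  "E_T": 0.0,
  "g_GiTh": 0.003,
  "E_GiTh": -85.0,
  "p_theta": -60.0,
  "p_sigma": 6.2,
  "w_theta": -77.0,
  "w_sigma": -5.0,
  "tau_w_base": 28.0,
  "tau_w_scale": 1.0,
  "tau_w_theta": -25.0,
  "tau_w_sigma": 10.5,
  "phi": 1.0
}
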