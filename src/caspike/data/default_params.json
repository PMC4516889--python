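{
 "C_d_pF": 100.0,
 "C_p_pF": 150.0,
 "C_s_pF": 50.0,
 "J_ap_d_pA": 2000.0,
 "J_ap_p_pA": 0.0,
 "U_ca_mV": 120.0,
 "U_e_mV": 0.0,
 "U_i_mV": -80.0,
 "U_l_d_mV": -70.0,
 "U_l_p_mV": -70.0,
 "U_l_s_mV": -70.0,
 "V_peak_mV": 30.0,
 "bap_delay_d_ms": 2.0,
 "bap_delay_p_ms": 1.0,
 "g_ca_nS": 20.0,
 "g_l_d_nS": 10.0,
 "g_l_p_nS": 10.0,
 "g_l_s_nS": 10.0,
 "g_pd_nS": 20.0,
 "g_ref_nS": 150.0,
 "g_sp_nS": 30.0,
 "h_half_mV": -24.0,
 "h_slope_per_mV": 0.5,
 "m_half_mV": -21.0,
 "m_slope_per_mV": -1.0,
 "t_ref_ms": 2.0,
 "tau_ap_ms": 1.0,
 "tau_e_ms": 1.0,
 "tau_h_ms": 12.0,
 "tau_i_ms": 2.0,
 "tau_m_ms": 0.4,
 "tau_th_ms": 10.0,
 "theta_base_mV": -45.0,
 "theta_plus_mV": 6.0
}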