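name,value,param_class
k_syn_rela,12.0,expression
k_syn_crel,6.0,expression
k_syn_relb,1.5,expression
k_syn_p105,30.0,expression
k_syn_p100,10.0,expression
k_syn_ikba,1.0,expression
k_syn_ikbe,0.3,expression
k_ind_ikba,360.0,induction
k_ind_ikbe,3.0,induction
k_ind_relb,6.0,induction
K_nfkb,12.0,induction
n_nfkb,4.0,induction
k_proc_p105,0.6,catalysis
k_proc_p100,2.0,catalysis
k_ikk_ikba,12.0,catalysis
k_ikk_ikbe,0.05,catalysis
k_turn_ikb,0.06,catalysis
k_ikk_ikba_free,12.0,catalysis
k_ikk_ikbe_free,0.1,catalysis
k_on_a50,0.12,binding
k_off_a50,3.0,binding
k_on_c50,1.2,binding
k_off_c50,0.3,binding
k_on_b52,0.12,binding
k_off_b52,3.0,binding
k_on_p50_p50,0.03,binding
k_off_p50_p50,3.0,binding
k_on_dimer_w,0.006,binding
k_off_dimer_w,6.0,binding
k_on_p100_relb,0.06,binding
k_off_p100_relb,0.6,binding
k_b_ikba_a50,5.0,binding
k_b_ikba_c50,0.005,binding
k_b_ikbe_a50,0.005,binding
k_b_ikbe_c50,0.5,binding
k_cap_ikba_a50,8.0,binding
k_cap_ikba_c50,0.3,binding
k_cap_ikbe_a50,0.3,binding
k_cap_ikbe_c50,8.0,binding
k_imp_a50,120.0,transport
K_imp_a50,800.0,transport
k_imp_c50,30.0,transport
K_imp_c50,100.0,transport
k_imp_generic,30.0,transport
K_imp_generic,300.0,transport
k_exp_dimer,0.05,transport
k_deg_monomer,0.12,degradation
k_deg_ikb_free,1.2,degradation
k_deg_dimer,0.02,degradation
k_deg_complex,0.02,degradation
NEMO_IKK,0.05,input
NIK,0.05,input
n_imp_one,1.0,transport
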