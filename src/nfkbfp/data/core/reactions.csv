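name,reactants,products,rate_law,parameters,modifiers
syn_rela,,RelA,constant_source,k_syn_rela,
syn_crel,,cRel,constant_source,k_syn_crel,
syn_relb,,RelB,constant_source,k_syn_relb,
syn_p105,,p105,constant_source,k_syn_p105,
syn_p100,,p100,constant_source,k_syn_p100,
syn_ikba,,IkBa,constant_source,k_syn_ikba,
syn_ikbe,,IkBe,constant_source,k_syn_ikbe,
ind_ikba,,IkBa,hill_activation,k_ind_ikba;K_nfkb;n_nfkb,nRelAp50
ind_ikbe,,IkBe,hill_activation,k_ind_ikbe;K_nfkb;n_nfkb,ncRelp50
ind_relb,,RelB,hill_activation,k_ind_relb;K_nfkb;n_nfkb,nRelAp50;ncRelp50
proc_p105,p105,p50,mass_action,k_proc_p105,
proc_p100,p100,p52,activation,k_proc_p100,NIK
proc_p100_relb,p100_RelB,RelB + p52,activation,k_proc_p100,NIK
dim_relap50_f,RelA + p50,RelAp50,mass_action,k_on_a50,
dim_relap50_r,RelAp50,RelA + p50,mass_action,k_off_a50,
dim_crelp50_f,cRel + p50,cRelp50,mass_action,k_on_c50,
dim_crelp50_r,cRelp50,cRel + p50,mass_action,k_off_c50,
dim_relbp52_f,RelB + p52,RelBp52,mass_action,k_on_b52,
dim_relbp52_r,RelBp52,RelB + p52,mass_action,k_off_b52,
dim_p50p50_f,2 p50,p50p50,mass_action,k_on_p50_p50,
dim_p50p50_r,p50p50,2 p50,mass_action,k_off_p50_p50,
seq_relb,p100 + RelB,p100_RelB,mass_action,k_on_p100_relb,
seq_relb_r,p100_RelB,p100 + RelB,mass_action,k_off_p100_relb,
bind_ikba_a50,IkBa + RelAp50,IkBa_RelAp50,mass_action,k_b_ikba_a50,
cap_ikba_a50,IkBa + nRelAp50,IkBa_RelAp50,mass_action,k_cap_ikba_a50,
rel_ikba_a50,IkBa_RelAp50,RelAp50,activation,k_ikk_ikba,NEMO_IKK
turn_ikba_a50,IkBa_RelAp50,RelAp50,mass_action,k_turn_ikb,
bind_ikbe_a50,IkBe + RelAp50,IkBe_RelAp50,mass_action,k_b_ikbe_a50,
cap_ikbe_a50,IkBe + nRelAp50,IkBe_RelAp50,mass_action,k_cap_ikbe_a50,
rel_ikbe_a50,IkBe_RelAp50,RelAp50,activation,k_ikk_ikbe,NEMO_IKK
turn_ikbe_a50,IkBe_RelAp50,RelAp50,mass_action,k_turn_ikb,
bind_ikba_c50,IkBa + cRelp50,IkBa_cRelp50,mass_action,k_b_ikba_c50,
cap_ikba_c50,IkBa + ncRelp50,IkBa_cRelp50,mass_action,k_cap_ikba_c50,
rel_ikba_c50,IkBa_cRelp50,cRelp50,activation,k_ikk_ikba,NEMO_IKK
turn_ikba_c50,IkBa_cRelp50,cRelp50,mass_action,k_turn_ikb,
bind_ikbe_c50,IkBe + cRelp50,IkBe_cRelp50,mass_action,k_b_ikbe_c50,
cap_ikbe_c50,IkBe + ncRelp50,IkBe_cRelp50,mass_action,k_cap_ikbe_c50,
rel_ikbe_c50,IkBe_cRelp50,cRelp50,activation,k_ikk_ikbe,NEMO_IKK
turn_ikbe_c50,IkBe_cRelp50,cRelp50,mass_action,k_turn_ikb,
deg_ikba_ikk,IkBa,,activation,k_ikk_ikba_free,NEMO_IKK
deg_ikbe_ikk,IkBe,,activation,k_ikk_ikbe_free,NEMO_IKK
imp_relap50,RelAp50,nRelAp50,hill_activation,k_imp_a50;K_imp_a50;n_imp_one,RelAp50
exp_relap50,nRelAp50,RelAp50,mass_action,k_exp_dimer,
imp_crelp50,cRelp50,ncRelp50,hill_activation,k_imp_c50;K_imp_c50;n_imp_one,cRelp50
exp_crelp50,ncRelp50,cRelp50,mass_action,k_exp_dimer,
imp_relbp52,RelBp52,nRelBp52,hill_activation,k_imp_generic;K_imp_generic;n_imp_one,RelBp52
exp_relbp52,nRelBp52,RelBp52,mass_action,k_exp_dimer,
imp_p50p50,p50p50,np50p50,hill_activation,k_imp_generic;K_imp_generic;n_imp_one,p50p50
exp_p50p50,np50p50,p50p50,mass_action,k_exp_dimer,
deg_rela,RelA,,mass_action,k_deg_monomer,
deg_crel,cRel,,mass_action,k_deg_monomer,
deg_relb,RelB,,mass_action,k_deg_monomer,
deg_p105,p105,,mass_action,k_deg_monomer,
deg_p50,p50,,mass_action,k_deg_monomer,
deg_p100,p100,,mass_action,k_deg_monomer,
deg_p52,p52,,mass_action,k_deg_monomer,
deg_ikba,IkBa,,mass_action,k_deg_ikb_free,
deg_ikbe,IkBe,,mass_action,k_deg_ikb_free,
deg_relap50,RelAp50,,mass_action,k_deg_dimer,
deg_nrelap50,nRelAp50,,mass_action,k_deg_dimer,
deg_crelp50,cRelp50,,mass_action,k_deg_dimer,
deg_ncrelp50,ncRelp50,,mass_action,k_deg_dimer,
deg_relbp52,RelBp52,,mass_action,k_deg_dimer,
deg_nrelbp52,nRelBp52,,mass_action,k_deg_dimer,
deg_p50p50,p50p50,,mass_action,k_deg_dimer,
deg_np50p50,np50p50,,mass_action,k_deg_dimer,
deg_ikba_relap50,IkBa_RelAp50,,mass_action,k_deg_complex,
deg_ikbe_relap50,IkBe_RelAp50,,mass_action,k_deg_complex,
deg_ikba_crelp50,IkBa_cRelp50,,mass_action,k_deg_complex,
deg_ikbe_crelp50,IkBe_cRelp50,,mass_action,k_deg_complex,
deg_p100_relb,p100_RelB,,mass_action,k_deg_complex,
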