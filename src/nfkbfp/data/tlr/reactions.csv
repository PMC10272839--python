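name,reactants,products,rate_law,parameters,modifiers
syn_tlr9,,TLR9,constant_source,k_syn_tlr9,
deg_tlr9,TLR9,,mass_action,k_deg_tlr9,
bind_cpg,TLR9,TLR9a,activation,k_cpg_bind,CpG
unbind_cpg,TLR9a,TLR9,mass_action,k_cpg_unbind,
int_tlr9a,TLR9a,,mass_action,k_int_tlr9a,
act_myd88,MyD88i,MyD88a,activation,k_myd88_act,TLR9a
self_myd88,MyD88i,MyD88a,activation,k_myd88_self,MyD88a
basal_myd88,MyD88i,MyD88a,mass_action,k_myd88_basal,
inact_myd88,MyD88a,MyD88i,mass_action,k_myd88_inact,
act_traf6,TRAF6i,TRAF6a,activation,k_traf6_act,MyD88a
inact_traf6,TRAF6a,TRAF6i,mass_action,k_traf6_inact,
act_tak1,TAK1i,TAK1a,activation,k_tak1_act,TRAF6a
inact_tak1,TAK1a,TAK1i,mass_action,k_tak1_inact,
act_ikk,IKKi,IKKa,activation,k_ikk_act,TAK1a
off_ikk,IKKa,IKKr,mass_action,k_ikk_off,
rec_ikk,IKKr,IKKi,mass_action,k_ikk_rec,
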