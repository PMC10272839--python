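name,value,param_class
CpG,0.0,input
k_syn_tlr9,10.0,expression
k_deg_tlr9,0.1,degradation
k_cpg_bind,10.0,binding
k_cpg_unbind,0.5,binding
k_int_tlr9a,2.0,degradation
k_myd88_act,0.02,catalysis
k_myd88_self,0.001,catalysis
k_myd88_basal,0.002,catalysis
k_myd88_inact,1.0,catalysis
k_traf6_act,0.03,catalysis
k_traf6_inact,1.0,catalysis
k_tak1_act,0.03,catalysis
k_tak1_inact,1.0,catalysis
k_ikk_act,0.1,catalysis
k_ikk_off,4.0,catalysis
k_ikk_rec,0.04,catalysis
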