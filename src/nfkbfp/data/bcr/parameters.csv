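name,value,param_class
k_bcr_basal,1.0,input
k_bcr_decay,1.0,degradation
k_cbm_act,0.005,catalysis
k_cbm_inact,1.0,catalysis
k_tak1_act,0.03,catalysis
k_tak1_inact,1.0,catalysis
k_ikk_act,0.1,catalysis
k_ikk_off,4.0,catalysis
k_ikk_rec,0.04,catalysis
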