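name,reactants,products,rate_law,parameters,modifiers
engage_bcr,,BCRe,constant_source,k_bcr_basal,
decay_bcr,BCRe,,mass_action,k_bcr_decay,
act_cbm,CBMi,CBMa,activation,k_cbm_act,BCRe
inact_cbm,CBMa,CBMi,mass_action,k_cbm_inact,
act_tak1,TAK1i,TAK1a,activation,k_tak1_act,CBMa
inact_tak1,TAK1a,TAK1i,mass_action,k_tak1_inact,
act_ikk,IKKi,IKKa,activation,k_ikk_act,TAK1a
off_ikk,IKKa,IKKr,mass_action,k_ikk_off,
rec_ikk,IKKr,IKKi,mass_action,k_ikk_rec,
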