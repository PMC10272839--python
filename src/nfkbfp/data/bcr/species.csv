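name,compartment,initial_amount
BCRe,membrane,0.0
CBMi,cytoplasm,100.0
CBMa,cytoplasm,0.0
TAK1i,cytoplasm,100.0
TAK1a,cytoplasm,0.0
IKKi,cytoplasm,100.0
IKKa,cytoplasm,0.0
IKKr,cytoplasm,0.0
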