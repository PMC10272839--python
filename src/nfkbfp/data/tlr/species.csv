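name,compartment,initial_amount
TLR9,membrane,100.0
TLR9a,membrane,0.0
MyD88i,cytoplasm,100.0
MyD88a,cytoplasm,0.0
TRAF6i,cytoplasm,100.0
TRAF6a,cytoplasm,0.0
TAK1i,cytoplasm,100.0
TAK1a,cytoplasm,0.0
IKKi,cytoplasm,100.0
IKKa,cytoplasm,0.0
IKKr,cytoplasm,0.0
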