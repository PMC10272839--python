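name,compartment,initial_amount
RelA,cytoplasm,0.0
cRel,cytoplasm,0.0
RelB,cytoplasm,0.0
p105,cytoplasm,0.0
p50,cytoplasm,0.0
p100,cytoplasm,0.0
p52,cytoplasm,0.0
IkBa,cytoplasm,0.0
IkBe,cytoplasm,0.0
p100_RelB,cytoplasm,0.0
RelAp50,cytoplasm,0.0
nRelAp50,nucleus,0.0
cRelp50,cytoplasm,0.0
ncRelp50,nucleus,0.0
RelBp52,cytoplasm,0.0
nRelBp52,nucleus,0.0
p50p50,cytoplasm,0.0
np50p50,nucleus,0.0
IkBa_RelAp50,cytoplasm,0.0
IkBe_RelAp50,cytoplasm,0.0
IkBa_cRelp50,cytoplasm,0.0
IkBe_cRelp50,cytoplasm,0.0
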