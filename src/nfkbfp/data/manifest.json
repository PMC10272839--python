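{
 "core": {
  "n_species": 22,
  "n_parameters": 53,
  "n_reactions": 71,
  "subunit_moieties": {
   "RelA": {
    "RelA": 1,
    "RelAp50": 1,
    "nRelAp50": 1,
    "IkBa_RelAp50": 1,
    "IkBe_RelAp50": 1
   },
   "RelB": {
    "RelB": 1,
    "p100_RelB": 1,
    "RelBp52": 1,
    "nRelBp52": 1
   },
   "cRel": {
    "cRel": 1,
    "cRelp50": 1,
    "ncRelp50": 1,
    "IkBa_cRelp50": 1,
    "IkBe_cRelp50": 1
   },
   "p50": {
    "p50": 1,
    "p105": 1,
    "RelAp50": 1,
    "nRelAp50": 1,
    "IkBa_RelAp50": 1,
    "IkBe_RelAp50": 1,
    "cRelp50": 1,
    "ncRelp50": 1,
    "IkBa_cRelp50": 1,
    "IkBe_cRelp50": 1,
    "p50p50": 2,
    "np50p50": 2
   },
   "p52": {
    "p52": 1,
    "p100": 1,
    "p100_RelB": 1,
    "RelBp52": 1,
    "nRelBp52": 1
   }
  }
 },
 "tlr": {
  "n_species": 11,
  "n_parameters": 17,
  "n_reactions": 16
 },
 "bcr": {
  "n_species": 8,
  "n_parameters": 9,
  "n_reactions": 9
 }
}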