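# Enzyme-name -> candidate reaction ids, matched against whichever model is
# loaded. Exactly one candidate must be present in a given model; zero or
# several is a hard error. Genome-scale candidates follow BiGG naming across
# common model versions; the FERM_* ids are the lumped toy-network modes that
# carry the same enzyme's flux.
ack:
  - ACKr
  - ACK
  - FERM_MIX
pfl:
  - PFL
  - PFLi
  - FERM_MIX
pta:
  - PTAr
  - PTA
  - FERM_MIX
fum:
  - FUM
gnd:
  - GND
gdh:
  - GLUDy
mthfd:
  - MTHFD
cbm:
  - CBMKr
  - CBMK
glucose_exchange:
  - EX_glc__D_e
  - EX_glc_e
  - EX_glc(e)
  - EX_glc
glucokinase:
  - HEX1
  - GLUK
  - GLCK
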