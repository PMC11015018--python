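# Remote-sensing count of COPT planets (continents + oceans + plate
# tectonics coexisting for L_COPT = 5e8 yr).
name: copt
stages: [foc, fpt, copt]
copt:
  lifetime: 5.0e+8
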