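# Sequential speciation chain over a 1000-Myr plate-tectonic era.
name: speciation
stages: [speciation]
seed: 20240101
speciation:
  speciation_rate: 0.5
  extinction_rate: 0.0
  horizon: 1000.0
  n_reps: 2000
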