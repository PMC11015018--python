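# Modified Drake equation: f_i split into f_oc * f_pt, with Monte Carlo
# propagation over the 1961 ranges.
name: modified_acc
stages: [foc, fpt, drake]
seed: 20240101
drake:
  monte_carlo:
    n_samples: 100000
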