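# Classic 1961 'educated guess' ranges with f_i = 1 (interval evaluation only).
name: drake1961
stages: [drake]
drake:
  foc_bounds: [1.0, 1.0]
  fpt: 1.0
  base_range: [200.0, 5.0e+7]
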