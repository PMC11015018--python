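# The headline desk-scale chain: permitted windows, f_oc ratio bounds,
# f_pt upper bound, f_i product, and the rescaled ACC range.
name: paper_headline
stages: [water, foc, fpt, drake]
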