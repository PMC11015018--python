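# Single-lid to plate-tectonics transition timescales: mosaic assembly from
# trench-lengthening rates plus the two event-bracketed durations.
name: tectonic
stages: [tectonic]
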