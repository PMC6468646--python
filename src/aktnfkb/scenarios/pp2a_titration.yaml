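# PP2A mutation/loss: phosphatase level titrated between 0 and 11 nM
name: pp2a_titration
kind: species_set
species: PP2A
range_nM: [0.0, 11.0]
default_level: 0.0
grid: [0.0, 2.75, 5.5, 8.25, 11.0]
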