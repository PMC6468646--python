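# PI3K overexpression: total PI3K set between 10 and 100 nM
name: pi3k_overexpression
kind: species_set
species: PI3K
range_nM: [10.0, 100.0]
default_level: 100.0
grid: [10.0, 40.0, 70.0, 100.0]
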