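# EGFR overexpression: receptor level set between 80 and 360 nM
name: egfr_overexpression
kind: species_set
species: EGFR
range_nM: [80.0, 360.0]
default_level: 360.0
grid: [80.0, 160.0, 240.0, 360.0]
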