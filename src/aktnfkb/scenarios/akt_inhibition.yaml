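# Akt inhibition: activity multiplier on both Akt-activating steps,
# the in silico analogue of PI3K-inhibitor treatment or kinase-dead Akt
name: akt_inhibition
kind: rate_scaling
rate_reactions: [akt_phos_t308, akt_phos_s473]
range_mult: [0.0, 1.0]
default_level: 0.1
grid: [0.0, 0.25, 0.5, 0.75, 1.0]
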