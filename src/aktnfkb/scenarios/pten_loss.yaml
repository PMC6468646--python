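# PTEN loss: eliminate the PTEN-catalyzed dephosphorylation of PIP3
name: pten_loss
kind: reaction_deletion
deleted_reaction: pten_pip3_dephos
default_level: null
grid: [null]
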