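# dihydroflavonol 4-reductase: substrate-specificity annotation
@anchor substrate-binding 131 26
133 NDLA DFR-substrate-site
@spec substrate-binding 3 N accepts dihydrokaempferol, dihydroquercetin, dihydromyricetin
@spec substrate-binding 3 D reduced dihydrokaempferol acceptance
@spec substrate-binding 3 L dihydrokaempferol preference, reduced dihydromyricetin processing
@spec substrate-binding 3 A dihydrokaempferol preference, reduced dihydromyricetin processing
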