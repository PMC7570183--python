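# chalcone synthase: diagnostic residues and malonyl-CoA-binding motif
166 Q CHS-diagnostic-Q166
167 Q CHS-diagnostic-Q167
313-329 malonyl-CoA-binding-motif 0.6
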