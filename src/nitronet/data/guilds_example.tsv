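genus	guild
Sphingomonas	ammonia-oxidizer
Lysobacter	nitrifier
Nitrospira	nitrifier
Nocardioides	denitrifier
Gaiella	denitrifier
Ensifer	N-fixer
Blastococcus	N-fixer
Pseudolabrys	N-fixer
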