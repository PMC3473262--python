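code	name	is_outgroup	is_reference_anchor
At	Arabidopsis thaliana		yes
Pt	Populus trichocarpa
Os	Oryza sativa
Pp	Physcomitrella patens
Cr	Chlamydomonas reinhardtii
Syn	Synechocystis sp. PCC6803	yes
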