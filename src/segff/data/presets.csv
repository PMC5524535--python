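category,term_id,resource,label
ribosome,GO:0005840,GO,ribosome
ribosome,GO:0005761,GO,mitochondrial ribosome
ribosome,GO:0005763,GO,mitochondrial small ribosomal subunit
ribosome,GO:0005762,GO,mitochondrial large ribosomal subunit
proteasome,GO:0000502,GO,proteasome complex
proteasome,GO:0005839,GO,proteasome core complex
proteasome,GO:0008540,GO,proteasome regulatory particle base subcomplex
chaperonin,GO:0005832,GO,chaperonin-containing T-complex
chaperonin,GO:0005524,GO,ATP binding
chaperonin,GO:0051082,GO,unfolded protein binding
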