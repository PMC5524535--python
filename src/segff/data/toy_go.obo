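format-version: 1.2
ontology: segff-toy-go
remark: synthetic 12-term slice of Gene Ontology cellular_component for offline search and tests

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0043226
name: organelle
namespace: cellular_component
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005739
name: mitochondrion
namespace: cellular_component
synonym: "mitochondria" EXACT []
is_a: GO:0043226 ! organelle

[Term]
id: GO:0032991
name: protein-containing complex
namespace: cellular_component
synonym: "macromolecular complex" EXACT []
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005840
name: ribosome
namespace: cellular_component
synonym: "ribosomal RNA-protein complex" RELATED []
is_a: GO:0032991 ! protein-containing complex

[Term]
id: GO:0005761
name: mitochondrial ribosome
namespace: cellular_component
synonym: "mitoribosome" EXACT []
is_a: GO:0005840 ! ribosome

[Term]
id: GO:0005763
name: mitochondrial small ribosomal subunit
namespace: cellular_component
is_a: GO:0005761 ! mitochondrial ribosome

[Term]
id: GO:0005762
name: mitochondrial large ribosomal subunit
namespace: cellular_component
is_a: GO:0005761 ! mitochondrial ribosome

[Term]
id: GO:0000502
name: proteasome complex
namespace: cellular_component
synonym: "26S proteasome" EXACT []
is_a: GO:0032991 ! protein-containing complex

[Term]
id: GO:0005832
name: chaperonin-containing T-complex
namespace: cellular_component
synonym: "CCT particle" EXACT []
is_a: GO:0032991 ! protein-containing complex

[Term]
id: GO:0005737
name: cytoplasm
namespace: cellular_component
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0016020
name: membrane
namespace: cellular_component
is_a: GO:0005575 ! cellular_component
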