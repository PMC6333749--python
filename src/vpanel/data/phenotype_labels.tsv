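# Free-text phenotype label -> fixture ontology term id. Covers the index
# case's query criteria and common labels from the cohort table; mapping
# against a real ontology release is the user's responsibility.
label	term_id
Ataxia	HP:0001251
Seizures	HP:0001250
Esotropia	HP:0000565
Puberty and gonadal disorders	HP:0008373
Global developmental delay	HP:0001263
Autosomal recessive	HP:0000007
Autosomal dominant	HP:0000006
Intellectual disability	HP:0001249
Autism	HP:0000717
Microcephaly	HP:0000252
Dystonia	HP:0001332
Cerebellar atrophy	HP:0001272
Short stature	HP:0004322
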