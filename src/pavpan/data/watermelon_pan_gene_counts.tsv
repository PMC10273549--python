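category	count
reference_protein_coding_genes	22596
novel_protein_coding_genes	6249
core_and_softcore_genes	20050
shell_genes	7341
cloud_genes	1454
shell_genes_tested_in_gwas	6161
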