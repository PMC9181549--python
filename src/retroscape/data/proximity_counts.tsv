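gene_set	n_genes	n_with_primer_hit
steviol_glycoside	103	35
random_control	103	16
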