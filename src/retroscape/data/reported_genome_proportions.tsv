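superfamily	genome_percent	element_percent
Gypsy	36.7	70.68
Copia	18.7	28.88
undetermined	0.4	0.44
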