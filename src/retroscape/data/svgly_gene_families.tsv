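gene_family	n_genes_near_primer
UDP-glycosyltransferase	18
Ent-kaurene oxidase	5
Geranylgeranyl pyrophosphate synthase	3
Methyl-erythritol-phosphate cytidylyltransferase	3
Hydroxy-methylbutenyl diphosphate synthase (ferredoxin)	2
Deoxy-xylulose-phosphate reductoisomerase	1
Deoxy-xylulose-phosphate synthase	1
Isopentenyl-diphosphate Delta-isomerase	1
Methyl-erythritol cyclodiphosphate synthase	1
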