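code	direction	sequence
ANG_RNase+	forward	ATGGGACTTCGWTATTCTAGTG
ANG_1-	reverse	TTTGAGAGCGGGTCAGTCCAA
ANG_3-	reverse	CCATTCAATAACATCATCATCT
ANG_44-	reverse	TTATTTACTTATGTTATTTACCA
ANG_44+	forward	ATTGGTAAATAACATAAGTAAAT
ANG_4-	reverse	CACAAGCTTGTATACCCCAAG
ANG_5+	forward	TTCAAGAATCACACCCTCTA
ANG_55+	forward	TCATAACCTAGCCAAGACCT
ANG_55-	reverse	AGGTCTTGGCTAGGTTATGA
ANG_6+	forward	AACAAACGCGACAAACTAAAAC
ANG_gag-	reverse	CAATTCTCAAGTTTCGATACCA
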