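id_code	accession	origin	cultivated_in
1/4	MA1/4	Brasil	pot
1	MApt1	Brasil	pot
2	MA13/1	Brasil	pot
3	MApt2	Brasil	pot
4	MA10/1	Brasil	pot
5	MApt5	Brasil	pot
6	MA7/3	Brasil	pot
7	MApt3	Brasil	pot
8	MApt4	Brasil	pot
9	SV1	Brasil	pot
10	Criolla	Paraguay	pot
11	Sweet Herb	Paraguay	pot
A	PL	Israel	field
B	BR16	Brasil	pot
C	RGm	Italy	field
D	SL	Israel	field
E	Num	Italy	pot
F	CO	Israel	field
G	BR5	Brasil	field
H	SW30	Italy	field
I	BR1	Brasil	field
L	MASV4-2/2	Brasil	pot
M	Eirete	Paraguay	pot
B1	BR16	Brasil	pot
B3	BR16	Brasil	pot
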