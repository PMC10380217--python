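#outgroup=Outgroup
taxon_group	B	D	E	F	G	L	M	S	T	U	R	W	X
Outgroup	12	6	5	4	0	60-78	4	6	7	13	5	3	6
Acalyptaini	11	5	4	5	0	79	4	5	7	13	5	3	3-4
Litadeini	11	4	5	5	0	81	4	5	7	13	5	3	6
Tingini	11	5	4-5	5	0	63-79	4	5	7	13	5	3	5-6
Cantacaderinae	11	5	5	4	0	57	4	5	7	13	5	3	5
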