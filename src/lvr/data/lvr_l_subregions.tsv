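#outgroup=Outgroup
taxon_group	consensus_species	printed_total	L2	LA1	LA2	LB1	LB2	LC1	LC2	LD1	LD2	LE1	LE2
Outgroup	Adelphocoris_lineolatus	74	4	9	9	10	9	3	4	6	5	8	7
Acalyptaini	Acalypta_sauteri	79	4	10	9	11	10	4	4	5	5	8	8
Litadeini	Nobarnus_signatus	81	4	10	9	13	11	4	4	5	5	8	8
Tingini	Tingis_matsumurai	78	5	10	9	11	11	3	5	6	4	7	7
Cantacaderinae	Cantacader_lethierryi	57	4	9	9	0	0	7	5	7	7	4	5
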