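#outgroup=Outgroup
taxon_group	consensus_species	V2	V4	V7
Outgroup	Adelphocoris_lineolatus	198	317	91
Acalyptaini	Acalypta_sauteri	200	321	90
Litadeini	Nobarnus_signatus	202	323	90
Tingini	Tingis_matsumurai	200	320	90
Cantacaderinae	Cantacader_lethierryi	199	299	90
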