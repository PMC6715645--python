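accession	species	origin	two_n	ploidy	largest_um	smallest_um	size_ratio_printed	haploid_um	formula_printed	stebbins_printed	consistent_ratio
S_rufescens	Smilax rufescens	Ilha do Cardoso (SP)	32	2	5.62	1.84	3.05	54.24	7st+6.5sm+2.5m	3B	1
S_fluminensis_Uruana	Smilax fluminensis	Uruana (GO)	32	2	6.41	1.33	4.82	43.47	4st+10sm+2m	3C	1
S_fluminensis_Itirapina	Smilax fluminensis	Itirapina (SP)	32	2	6.48	1.31	4.95	43.32	5st+7sm+4m	3C	1
S_polyantha_Botucatu	Smilax polyantha	Botucatu (SP)	32	2	5.85	1.92	3.05	44.09	9st+3sm+4m	3B	1
S_polyantha_MogiGuacu	Smilax polyantha	Mogi Guacu (SP)	32	2	5.36	1.94	2.80	41.03	10.5st+2.5sm+3m	3B	0
S_brasiliensis	Smilax brasiliensis	Itapagipe (MG)	32	2	5.04	1.77	2.85	38.02	8st+6sm+2m	3B	1
S_campestris	Smilax campestris	Cacapava do Sul (RS)	32	2	6.20	1.95	3.18	43.44	5st+5sm+6m	3B	1
S_cissoides	Smilax cissoides	Feira de Santana (BA)	32	2	5.51	2.00	2.75	40.17	7st+7sm+2m	3B	1
S_goyazana	Smilax goyazana	Brasilia (DF)	64	4	4.85	1.61	3.01	79.25	2t+15.5st+8.5sm+6m	3B	1
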