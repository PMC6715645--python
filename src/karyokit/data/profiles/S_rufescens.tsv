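accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_rufescens	1	10.37	5.28	st	none	0
S_rufescens	2	9.64	4.13	st	none	0
S_rufescens	3	8.70	4.46	st	none	0
S_rufescens	4	8.23	3.41	st	none	0
S_rufescens	5	7.55	3.28	st	none	0
S_rufescens	6	7.08	3.00	st	none	0
S_rufescens	7	6.36	3.30	st	one_homolog	1
S_rufescens	8	6.03	2.56	sm	none	0
S_rufescens	9	5.82	2.82	sm	none	0
S_rufescens	10	5.06/5.06	2.17/1.67	sm/m	none	0
S_rufescens	11	4.75	2.15	sm	one_homolog	1
S_rufescens	12	4.57	1.99	sm	none	0
S_rufescens	13	4.35	1.92	sm	none	0
S_rufescens	14	4.09	1.84	sm	one_homolog	1
S_rufescens	15	3.87	1.53	m	none	0
S_rufescens	16	3.41	1.24	m	none	0
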