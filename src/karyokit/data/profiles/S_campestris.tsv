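accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_campestris	1	11.06	4.51	st	none	0
S_campestris	2	9.32	4.1	st	none	0
S_campestris	3	8.54	3.23	st	none	0
S_campestris	4	8.18	2.94	sm	none	0
S_campestris	5	7.47	3.18	st	none	0
S_campestris	6	7.25	2.27	sm	none	0
S_campestris	7	6.70	3.00	st	none	0
S_campestris	8	6.40	2.7	sm	none	0
S_campestris	9	5.65	1.99	sm	none	0
S_campestris	10	5.32	2.17	sm	one_homolog	0
S_campestris	11	4.63	1.5	m	none	0
S_campestris	12	4.14	1.50	m	none	0
S_campestris	13	4.14	1.38	m	none	0
S_campestris	14	3.85	1.5	m	one_homolog	0
S_campestris	15	3.81	1.62	m	none	0
S_campestris	16	3.47	1.4	m	none	0
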