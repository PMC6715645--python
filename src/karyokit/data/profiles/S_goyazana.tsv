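accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_goyazana	1	5.51	8.00	t	one_homolog	0
S_goyazana	2	5.51	7.5	t	none	0
S_goyazana	3	5.00	5.75	st	none	0
S_goyazana	4	4.50	4.35	st	none	0
S_goyazana	5	4.48	4.89	st	none	0
S_goyazana	6	4.38	5.01	st	none	0
S_goyazana	7	4.29	4.16	st	none	0
S_goyazana	8	4.28	4.00	st	none	0
S_goyazana	9	3.79	3.00	st	none	0
S_goyazana	10	3.69	3.17	st	none	0
S_goyazana	11	3.64	3.00	st	none	0
S_goyazana	12	3.59	2.7	sm	none	0
S_goyazana	13	3.45	3.44	st	none	0
S_goyazana	14	3.28	3.10	st	none	0
S_goyazana	15	3.18	3.03	st	none	0
S_goyazana	16	3.09	3.00	st	none	0
S_goyazana	17	2.94	3.00	st	none	0
S_goyazana	18	2.85	2.96	sm	none	0
S_goyazana	19	2.85	2.96	sm	none	0
S_goyazana	20	2.73	2.7	sm	none	0
S_goyazana	21	2.69	3.00	st	none	0
S_goyazana	22	2.17	1.83	sm	none	0
S_goyazana	23	2.09	1.5	m	none	0
S_goyazana	24	2.05	1.78	sm	none	0
S_goyazana	25	1.97	2.50	sm	none	0
S_goyazana	26	1.94	2.60	sm	none	0
S_goyazana	27	1.89/1.89	3.00/2.09	st/sm	none	0
S_goyazana	28	1.89	1.17	m	none	0
S_goyazana	29	1.85	1.18	m	none	0
S_goyazana	30	1.77	1.32	m	none	0
S_goyazana	31	1.71	1.43	m	none	0
S_goyazana	32	1.67	1.40	m	none	0
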