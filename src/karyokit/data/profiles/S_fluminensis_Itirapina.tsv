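accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_fluminensis_Itirapina	1	15.79	1.07	m	none	0
S_fluminensis_Itirapina	2	10.87	2.08	sm	none	0
S_fluminensis_Itirapina	3	8.67	3.00	st	none	0
S_fluminensis_Itirapina	4	8.35	2.68	sm	none	0
S_fluminensis_Itirapina	5	8.16	3.03	st	none	0
S_fluminensis_Itirapina	6	7.00	3.03	st	none	0
S_fluminensis_Itirapina	7	6.31	1.60	m	none	0
S_fluminensis_Itirapina	8	5.96	3.0	st	one_homolog	1
S_fluminensis_Itirapina	9	5.43	2.24	sm	none	0
S_fluminensis_Itirapina	10	5.04	2.49	sm	none	0
S_fluminensis_Itirapina	11	4.26	2.03	sm	none	0
S_fluminensis_Itirapina	12	4.24	3.00	st	none	0
S_fluminensis_Itirapina	13	4.09	1.84	sm	none	0
S_fluminensis_Itirapina	14	4.01	1.49	m	none	0
S_fluminensis_Itirapina	15	3.77	1.56	m	none	0
S_fluminensis_Itirapina	16	3.13	1.78	sm	none	0
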