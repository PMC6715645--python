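accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_fluminensis_Uruana	1	15.08	1.02	m	none	0
S_fluminensis_Uruana	2	11.32	2.02	sm	none	0
S_fluminensis_Uruana	3	9.25	3.17	st	none	0
S_fluminensis_Uruana	4	8.84	2.91	sm	none	0
S_fluminensis_Uruana	5	8.26	3.03	st	none	0
S_fluminensis_Uruana	6	6.50	4.00	st	none	0
S_fluminensis_Uruana	7	5.87	2.50	sm	none	0
S_fluminensis_Uruana	8	5.59	2.70	sm	none	0
S_fluminensis_Uruana	9	5.11	2.98	sm	none	0
S_fluminensis_Uruana	10	4.81	2.55	sm	none	0
S_fluminensis_Uruana	11	4.03	2.31	sm	none	0
S_fluminensis_Uruana	12	4.04	3.00	st	none	0
S_fluminensis_Uruana	13	3.95	1.77	sm	none	0
S_fluminensis_Uruana	14	3.77	1.49	m	none	0
S_fluminensis_Uruana	15	3.53	1.70	sm	none	0
S_fluminensis_Uruana	16	3.33	1.85	sm	none	0
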