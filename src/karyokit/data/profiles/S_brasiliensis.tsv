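accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_brasiliensis	1	11.82	6.00	st	none	0
S_brasiliensis	2	10.50	5.10	st	none	0
S_brasiliensis	3	10.00	4.00	st	none	0
S_brasiliensis	4	9.24	3.90	st	none	0
S_brasiliensis	5	8.74	3.38	st	none	0
S_brasiliensis	6	8.17	3.17	st	none	0
S_brasiliensis	7	7.61	3.00	st	none	0
S_brasiliensis	8	6.94	2.72	sm	none	0
S_brasiliensis	9	6.44	2.54	sm	none	0
S_brasiliensis	10	5.41	2.74	sm	none	0
S_brasiliensis	11	5.19	3.00	st	one_homolog	0
S_brasiliensis	12	4.89	1.89	sm	none	0
S_brasiliensis	13	4.89	2.00	sm	none	0
S_brasiliensis	14	4.80	1.78	sm	none	0
S_brasiliensis	15	4.65	1.47	m	none	0
S_brasiliensis	16	4.17	1.50	m	none	0
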