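accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_cissoides	1	10.33	4.60	st	none	0
S_cissoides	2	9.39	4.54	st	none	0
S_cissoides	3	8.18	3.00	st	none	0
S_cissoides	4	7.97	3.82	st	none	0
S_cissoides	5	7.70	2.79	sm	none	0
S_cissoides	6	7.24	3.44	st	none	0
S_cissoides	7	6.56	2.4	sm	none	0
S_cissoides	8	6.11	3.00	st	none	0
S_cissoides	9	5.82	3.00	st	none	0
S_cissoides	10	5.28	2.00	sm	none	0
S_cissoides	11	4.69	2.00	sm	none	0
S_cissoides	12	4.23	1.70	sm	none	0
S_cissoides	13	4.19	1.87	sm	none	0
S_cissoides	14	3.57	2.00	sm	none	0
S_cissoides	15	3.57	1.49	m	none	0
S_cissoides	16	3.50	1.50	m	none	0
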