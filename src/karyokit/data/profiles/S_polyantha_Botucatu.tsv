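accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_polyantha_Botucatu	1	11.80	6.10	st	none	0
S_polyantha_Botucatu	2	10.29	6.00	st	none	0
S_polyantha_Botucatu	3	9.68	5.00	st	none	0
S_polyantha_Botucatu	4	9.01	4.00	st	none	0
S_polyantha_Botucatu	5	8.29	4.00	st	none	0
S_polyantha_Botucatu	6	7.88	3.8	st	none	0
S_polyantha_Botucatu	7	6.99	3.10	st	none	0
S_polyantha_Botucatu	8	6.76	3.00	st	none	0
S_polyantha_Botucatu	9	5.94	2.11	sm	none	0
S_polyantha_Botucatu	10	5.21	2.43	sm	none	0
S_polyantha_Botucatu	11	5.00	1.59	m	none	0
S_polyantha_Botucatu	12	4.75	3.00	st	none	0
S_polyantha_Botucatu	13	4.56	2.50	sm	none	0
S_polyantha_Botucatu	14	4.43	1.45	m	none	0
S_polyantha_Botucatu	15	4.05	1.35	m	none	0
S_polyantha_Botucatu	16	3.90	1.24	m	none	0
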