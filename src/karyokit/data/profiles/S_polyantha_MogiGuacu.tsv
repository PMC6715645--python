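accession	rank	rel_length_pct	arm_ratio	type	satellite_seen	nor
S_polyantha_MogiGuacu	1	10.52	6.00	st	none	0
S_polyantha_MogiGuacu	2	9.71	6.00	st	none	0
S_polyantha_MogiGuacu	3	8.86	4.00	st	none	0
S_polyantha_MogiGuacu	4	8.15	3.50	st	none	0
S_polyantha_MogiGuacu	5	7.90	3.50	st	none	0
S_polyantha_MogiGuacu	6	6.95	3.17	st	none	0
S_polyantha_MogiGuacu	7	6.85	3.17	st	none	0
S_polyantha_MogiGuacu	8	6.07	3.00	st	none	0
S_polyantha_MogiGuacu	9	5.95	3.00	st	none	0
S_polyantha_MogiGuacu	10	5.59	3.00	st	none	0
S_polyantha_MogiGuacu	11	4.91/4.91	2.00/3.00	sm/st	none	0
S_polyantha_MogiGuacu	12	4.37	2.04	sm	none	0
S_polyantha_MogiGuacu	13	4.34	2.00	sm	none	0
S_polyantha_MogiGuacu	14	3.88	1.60	m	none	0
S_polyantha_MogiGuacu	15	3.06	1.50	m	none	0
S_polyantha_MogiGuacu	16	3.02	1.24	m	none	0
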