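variable	level	overall_n	overall_pct	high_n	high_pct	low_n	low_pct
gender	female	186	35.1	76	34.5	110	35.5
gender	male	344	64.9	144	65.5	200	64.5
grade	G1	14	2.6	3	1.4	11	3.5
grade	G2	227	42.8	70	31.8	157	50.6
grade	G3	206	38.9	93	42.3	113	36.5
grade	G4	75	14.2	53	24.1	22	7.1
grade	GX	5	0.9	1	0.5	4	1.3
grade	Unknown	3	0.6	0	0.0	3	1.0
stage	Stage I	265	50.0	76	34.5	189	61.0
stage	Stage II	57	10.8	25	11.4	32	10.3
stage	Stage III	123	23.2	61	27.7	62	20.0
stage	Stage IV	82	15.5	55	25.0	27	8.7
stage	Unknown	3	0.6	3	1.4	0	0.0
t_stage	T1	21	4.0	8	3.6	13	4.2
t_stage	T1a	140	26.4	35	15.9	105	33.9
t_stage	T1b	110	20.8	35	15.9	75	24.2
t_stage	T2	55	10.4	22	10.0	33	10.6
t_stage	T2a	10	1.9	5	2.3	5	1.6
t_stage	T2b	4	0.8	4	1.8	0	0.0
t_stage	T3	5	0.9	2	0.9	3	1.0
t_stage	T3a	120	22.6	71	32.3	49	15.8
t_stage	T3b	52	9.8	27	12.3	25	8.1
t_stage	T3c	2	0.4	2	0.9	0	0.0
t_stage	T4	11	2.1	9	4.1	2	0.6
m_stage	M0	420	79.2	152	69.1	268	86.5
m_stage	M1	78	14.7	52	23.6	26	8.4
m_stage	MX	30	5.7	16	7.3	14	4.5
m_stage	Unknown	2	0.4	0	0.0	2	0.6
n_stage	N0	239	45.1	107	48.6	132	42.6
n_stage	N1	16	3.0	12	5.5	4	1.3
n_stage	NX	275	51.9	101	45.9	174	56.1
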