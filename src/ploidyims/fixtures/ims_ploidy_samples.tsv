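id	group	sex	age	T	N	M	G	UICC	classification	cells	stem_lines	exceeding_5c
T1	tumor	w	70	2	0	0	3	1	diploid	1598	2.02	1
T2	tumor	m	71	3	0	0	2	2	diploid	8284	1.96	2
T3	tumor	m	66	4	2	1	3	4	diploid	4791	1.97	2
T4	tumor	m	69	2	0	0	3	1	aneuploid	1083	2.01 + 5.67	162
T5	tumor	w	64	3	1	0	2	3	aneuploid	3621	2.03	30
T6	tumor	w	62	4	1	1	2	4	aneuploid	1912	1.95 + 3.27	142
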