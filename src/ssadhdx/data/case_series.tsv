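subject_id	cohort	age_years	sex	clinical_flags	urine_ghb	ghb_reported_elevated	imaging_suggestive	allele1	allele2	class1	class2
1	referral	0.5	M	developmental_delay;hypotonia		1	0	c.668G>A	c.668G>A	pathogenic	pathogenic
2	referral	0.5	M	developmental_delay;hypotonia;failure_to_thrive		1	0	c.1597G>A	c.1015-2A>C	pathogenic	pathogenic
3	referral	1	F	developmental_delay;hypotonia		0	0	c.768_784del	c.768_784del	pathogenic	pathogenic
4	referral	1	F	developmental_delay;hypotonia		1	1	c.649G>A	c.649G>A	pathogenic	pathogenic
5	referral	1	F	developmental_delay;hypotonia;abnormal_urine_organic_acids		0	0	c.379_380del	c.379_380del	pathogenic	pathogenic
6	referral	1	F	developmental_delay;hypotonia;abnormal_urine_organic_acids		0	1	c.1226G>A	c.1323dup	pathogenic	pathogenic
7	referral	2	M	seizures;microcephaly;hypotonia;developmental_delay		0	0	c.1501_1503del	c.1501_1503del	pathogenic	pathogenic
8	referral	4	F	speech_delay;developmental_delay;abnormal_urine_organic_acids		0	0	c.967_968dup	c.1597G>A	pathogenic	pathogenic
9	referral	5	M	developmental_delay;ataxia;hypotonia;speech_delay		0	1	c.111_122delinsG	c.608C>T	pathogenic	pathogenic
10	referral	7	F	stroke		1	1	c.416C>A	c.1015-2A>C	pathogenic	pathogenic
11	referral	10	M	developmental_delay;hypotonia		1	0	c.612G>A	c.1234C>T	pathogenic	pathogenic
12	referral	11	F	developmental_delay		1	0	c.380G>A	c.431C>A	pathogenic	pathogenic
13	referral	12	F	developmental_delay;hypotonia		1	0	c.612G>A	c.1234C>T	pathogenic	pathogenic
14	referral	22	F			0	0	c.803G>A	c.1558G>C	pathogenic	pathogenic
15	referral	25	F			0	0	c.803G>A	c.1558G>C	pathogenic	pathogenic
16	referral	44	M	developmental_delay;hypotonia;seizures;autistic_features		0	0	c.1597G>A	c.1234C>T	pathogenic	pathogenic
17	biobank	2	F		4323.0	0	0	c.612G>A	c.1597G>A	pathogenic	pathogenic
18	biobank	5	M		431.4	0	0	c.104_127del	c.1015-2A>C	pathogenic	pathogenic
19	biobank	7	F		228.0	0	0	c.612G>A	c.803G>A	pathogenic	pathogenic
20	biobank	10	F		302.0	0	0	c.608C>T	c.608C>T	pathogenic	pathogenic
21	biobank	11	F		1431.0	0	0	c.1226G>A	c.1323dup	pathogenic	pathogenic
22	biobank	25	M		74.5	0	0	c.754G>T	c.754G>T	pathogenic	pathogenic
23	biobank	27	M		81.2	0	0	c.612G>A	c.612G>A	pathogenic	pathogenic
24	biobank	41	M		60.8	0	0	c.612G>A	c.1015-2A>C	pathogenic	pathogenic
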