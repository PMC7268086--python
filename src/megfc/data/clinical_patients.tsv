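subject_id	sex	age_years	onset_age_years	duration_years	seizure_frequency_text	histopathology_label	mri_label	outcome_label	follow_up_months
1	F	23	6	17	10-30/day	FCDIIb	Negative	seizure_free	39
2	M	23	19	4	1-2/month	FCDI	Negative	seizure_free	32
3	M	21	16	5	30-40/day	FCDIIa	Negative	seizure_free	46
4	F	23	3	20	1-4/day	FCDI	Negative	seizure_free	39
5	F	24	7	17	15-20/month	FCDIIa	Negative	seizure_free	72
6	M	27	10	17	1-4/day	FCDI	Negative	seizure_free	12
7	M	14	6	8	3-4/day	FCDIIb	Postoperative changes of left frontal	seizure_free	36
8	M	18	10	8	2-4/day	FCDIIId	Right anterior temporal hippocampus after resection	seizure_free	60
9	M	26	8	18	20-40/day	FCDI	Negative	seizure_free	38
10	M	22	5	17	20-40/day	MCD	Negative	seizure_free	84
11	M	10	1	9	2-3/day	FCDIa	Negative	reduced	23
12	M	22	13	9	3-6/day	FCDIIId	Negative	seizure_free	68
13	F	30	15	15	2-3/day	FCDI	Negative	reduced	39
14	M	17	11	6	2-20/day	FCDI	Negative	reduced	39
15	M	18	7	11	1-2/day	FCDIIb	Negative	seizure_free	16
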