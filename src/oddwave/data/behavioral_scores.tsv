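test	subtest	control_mean	control_sd	dyslexia_mean	dyslexia_sd	n_control	n_dyslexia	printed_t	printed_d
KBIT-2	Matrices	114.75	13.28	107.00	15.25	24	24	1.88	0.54
WRMT-III	Word identification	110.17	7.87	90.63	9.39	24	24	7.82	2.26
WRMT-III	Word attack	101.50	8.29	78.83	9.95	24	24	8.58	2.48
WRMT-III	Listening comprehension	107.83	6.75	102.17	11.03	24	24	2.15	0.62
TOWRE-2	Sight word efficiency	108.63	12.37	89.71	9.42	24	24	5.96	1.72
TOWRE-2	Phonemic decoding efficiency	104.29	6.80	84.00	8.50	24	24	9.13	2.64
GORT-5	Oral reading index	105.75	8.76	85.08	11.65	24	24	6.94	2.01
CTOPP-2	Elision	9.63	1.91	7.92	2.55	24	24	2.63	0.76
CTOPP-2	Blending words	11.79	2.30	10.75	2.74	24	24	1.43	0.41
CTOPP-2	Non-word repetition	8.79	2.23	6.38	1.58	24	24	4.33	1.25
WAIS-IV	Digit span total	10.79	2.62	8.79	2.40	24	24	2.76	0.80
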