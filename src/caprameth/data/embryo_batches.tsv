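year	batch	stage	failure	success	c2	c4	c8plus	printed_ratio
2014	1	mature	86	150	NA	NA	NA	63.56
2014	1	clone	19	131	NA	NA	NA	87.33
2014	1	fusion	33	98	NA	NA	NA	74.81
2014	1	cleavage	44	54	0	47	7	55.10
2014	2	mature	65	118	NA	NA	NA	64.48
2014	2	clone	13	105	NA	NA	NA	88.98
2014	2	fusion	26	79	NA	NA	NA	75.24
2014	2	cleavage	18	61	0	42	19	77.22
2014	3	mature	50	85	NA	NA	NA	62.96
2014	3	clone	17	68	NA	NA	NA	80.00
2014	3	fusion	18	50	NA	NA	NA	73.53
2014	3	cleavage	29	21	0	12	9	42.00
2014	4	mature	41	82	NA	NA	NA	66.67
2014	4	clone	4	78	NA	NA	NA	95.12
2014	4	fusion	19	59	NA	NA	NA	75.64
2014	4	cleavage	25	34	0	14	20	57.63
2014	5	mature	40	56	NA	NA	NA	58.33
2014	5	clone	2	54	NA	NA	NA	96.43
2014	5	fusion	15	39	NA	NA	NA	72.22
2014	5	cleavage	19	20	0	6	14	51.28
2014	6	mature	30	35	NA	NA	NA	53.85
2014	6	clone	2	33	NA	NA	NA	94.29
2014	6	fusion	8	25	NA	NA	NA	75.76
2014	6	cleavage	13	12	0	4	8	48.00
2014	7	mature	50	68	NA	NA	NA	57.63
2014	7	clone	15	53	NA	NA	NA	77.94
2014	7	fusion	20	33	NA	NA	NA	62.26
2014	7	cleavage	23	10	0	9	1	30.30
2014	8	mature	32	117	NA	NA	NA	78.52
2014	8	clone	17	100	NA	NA	NA	85.47
2014	8	fusion	30	70	NA	NA	NA	70.00
2014	8	cleavage	42	28	0	20	8	40.00
2014	9	mature	46	70	NA	NA	NA	60.34
2014	9	clone	27	43	NA	NA	NA	61.43
2014	9	fusion	6	37	NA	NA	NA	86.05
2014	9	cleavage	23	14	0	8	6	37.84
2014	10	mature	28	42	NA	NA	NA	60.00
2014	10	clone	1	41	NA	NA	NA	97.62
2014	10	fusion	18	23	NA	NA	NA	56.10
2014	10	cleavage	15	8	0	8	0	34.78
2014	11	mature	16	49	NA	NA	NA	75.38
2014	11	clone	7	42	NA	NA	NA	85.71
2014	11	fusion	13	29	NA	NA	NA	69.05
2014	11	cleavage	14	15	0	13	2	51.72
2014	12	mature	53	39	NA	NA	NA	42.39
2014	12	clone	7	32	NA	NA	NA	82.05
2014	12	fusion	14	18	NA	NA	NA	56.25
2014	12	cleavage	5	13	0	9	4	72.22
2015	1	mature	27	79	NA	NA	NA	74.53
2015	1	clone	0	79	NA	NA	NA	100.00
2015	1	fusion	27	52	NA	NA	NA	65.82
2015	1	cleavage	40	12	12	0	0	23.08
2015	2	mature	54	130	NA	NA	NA	70.65
2015	2	clone	0	130	NA	NA	NA	100.00
2015	2	fusion	55	75	NA	NA	NA	57.69
2015	2	cleavage	66	9	9	0	0	12.00
2015	3	mature	46	119	NA	NA	NA	72.12
2015	3	clone	0	119	NA	NA	NA	100.00
2015	3	fusion	42	77	NA	NA	NA	64.71
2015	3	cleavage	35	42	42	0	0	54.55
2015	4	mature	51	93	NA	NA	NA	64.58
2015	4	clone	0	93	NA	NA	NA	100.00
2015	4	fusion	40	53	NA	NA	NA	56.99
2015	4	cleavage	43	4	4	0	0	8.51
2015	5	mature	36	107	NA	NA	NA	74.83
2015	5	clone	0	107	NA	NA	NA	100.00
2015	5	fusion	49	58	NA	NA	NA	54.21
2015	5	cleavage	41	17	17	0	0	29.31
2015	6	mature	28	135	NA	NA	NA	82.82
2015	6	clone	0	135	NA	NA	NA	100.00
2015	6	fusion	67	68	NA	NA	NA	50.37
2015	6	cleavage	30	32	32	0	0	51.61
2015	7	mature	33	118	NA	NA	NA	78.15
2015	7	clone	0	118	NA	NA	NA	100.00
2015	7	fusion	45	73	NA	NA	NA	61.86
2015	7	cleavage	47	23	23	0	0	32.86
2015	8	mature	36	84	NA	NA	NA	70.00
2015	8	clone	0	84	NA	NA	NA	100.00
2015	8	fusion	21	63	NA	NA	NA	75.00
2015	8	cleavage	37	23	23	0	0	38.33
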