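year	group	oocytes	scnt_embryos	embryos_transferred	surrogates	pregnancies	live_births	surviving_offspring	females	males
2014	F1-1-NM	NA	NA	NA	NA	7	9	9	1	8
2014	F1-1-SCNT	1448	290	177	46	2	2	2	0	2
2014	F1-1-WT	NA	NA	NA	NA	4	7	7	1	6
2015	F1-2-NM	NA	NA	NA	NA	5	8	8	5	3
2015	F1-2-SCNT	1176	501	367	99	4	4	4	2	2
2015	F1-2-WT	NA	NA	NA	NA	6	10	10	3	7
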