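848	0	7	0	0	7	0	0	1	26	12	0
0	663	85	0	0	12	2	0	0	5	97	0
0	87	752	0	0	1	0	0	0	6	41	0
0	1	1	1073	0	0	14	11	2	0	0	0
0	3	0	0	410	0	7	6	1	3	3	3
2	0	1	20	0	688	10	6	0	21	16	0
0	2	0	12	0	3	841	12	0	0	4	0
0	0	2	74	0	2	17	399	23	6	3	0
0	0	6	16	10	9	9	28	358	17	10	2
0	3	10	0	0	17	6	11	2	701	65	0
0	29	12	0	0	4	3	0	0	36	1046	0
0	0	2	1	4	0	2	2	4	0	2	184
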