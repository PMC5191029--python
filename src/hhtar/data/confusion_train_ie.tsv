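901	0	0	0	0	0	0	0	0	4	0	0
0	821	6	0	0	4	0	0	0	5	31	0
0	38	791	0	0	0	0	0	0	7	54	0
1	0	0	1082	0	0	12	3	8	0	0	0
0	0	0	0	441	0	0	0	0	0	0	0
1	0	0	1	0	720	2	0	0	33	11	0
0	0	0	5	1	0	872	0	0	0	0	0
0	6	22	76	0	2	13	337	45	10	17	0
0	5	21	29	0	5	16	31	341	8	10	1
0	0	2	1	0	16	5	9	2	755	28	0
0	10	18	0	0	8	0	0	0	16	1084	0
0	0	0	0	0	0	0	5	0	0	0	199
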