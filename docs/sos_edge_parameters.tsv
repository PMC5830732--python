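edge	target	regulator	sign	Q	R
1	lexA	recA	+	1.6273	1.6354
2	lexA	recF	+	0.58209	1.6833
3	lexA	rpoD	+	0.65218	1.8982
4	lexA	dinI	+	14.988	2.3757
5	lexA	ssB	-	17.705	2.2303
6	lexA	umuDC	-	272.67	1.5392
7	recA	recF	+	11.981	2.674
8	recA	rpoD	+	56.946	3.5452
9	recA	dinI	+	4.9391	1.4626
10	recA	lexA	-	34.691	1.3153
11	recA	ssB	-	4.779	1.8499
12	recA	umuDC	-	18.819	3.0102
13	recF	rpoD	+	61.511	4.9999
14	recF	rpoS	+	1.3297	1.1567
15	recF	ssB	-	8.4207	1.8104
16	recF	umuDC	-	11.72	2.117
17	rpoS	rpoD	+	14.013	2.049
18	rpoD	recF	+	11.867	1.8588
19	rpoD	recA	+	9.5381	2.2855
20	rpoD	dinI	+	1.7108	3.3169
21	rpoD	rpoH	+	4.6155	2.3944
22	rpoD	umuDC	-	23.779	2.9639
23	rpoD	ssB	-	39.778	1.7128
24	rpoD	lexA	-	3.0976	2.0704
25	umuDC	rpoD	+	1.5401	0.60901
26	umuDC	recF	+	0.9762	1.3191
27	umuDC	recA	+	13.822	4.0316
28	umuDC	dinI	-	1368600	1.8207
29	umuDC	ssB	-	0.50903	1.9367
30	umuDC	lexA	-	150.6	1.3081
31	dinI	rpoD	+	9.3893	1.9267
32	dinI	recF	+	134.06	1.9118
33	dinI	recA	+	15.778	2.3397
34	dinI	umuDC	-	2.4818	1.9367
35	dinI	ssB	-	8.9587	1.7976
36	dinI	lexA	-	40.718	1.3055
37	ssB	dinI	+	14.545	2.6053
38	ssB	rpoD	+	376.12	1.1819
39	ssB	recF	+	351.21	1.8328
40	ssB	recA	+	27.191	1.9916
41	ssB	umuDC	-	133.91	2.9068
42	ssB	lexA	-	9.7889	2.0699
43	rpoH	rpoD	+	14.225	2.041
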