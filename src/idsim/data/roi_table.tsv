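id	source	x	y	z	label
1	a_priori	-8	54	32	BA8/9
2	a_priori	-46	28	12	BA46
3	a_priori	-30	12	54	BA6
4	a_priori	-4	56	-4	BA10
5	exploratory	-36	-38	68	BA5
6	exploratory	-22	-12	18	Striatum
7	exploratory	22	-18	-14	BA35
8	exploratory	46	-50	-10	ITG
9	exploratory	-12	46	14	BA9
10	exploratory	-54	4	-26	BA21
11	exploratory	18	56	4	Forceps Minor
12	exploratory	-36	-6	16	BA13
13	exploratory	-36	-2	-14	Inferior Insula
14	exploratory	-32	12	-42	BA38
15	confirmatory	-26	-76	-42	Cerebellum
16	confirmatory	-44	-60	6	MTG
17	confirmatory	-58	-68	0	iLOC
18	confirmatory	-38	-84	20	sLOC
19	confirmatory	56	4	-18	STG
20	confirmatory	6	-52	48	Precuneus
21	confirmatory	8	56	38	Frontal Pole
22	confirmatory	48	24	28	MFG
23	confirmatory	46	-2	28	Precentral Gyrus
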