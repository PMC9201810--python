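# SYNTHETIC band map: standard major-band names laid out with
# uniform band widths within each hg19 arm. Band midpoints are
# approximate stand-ins for ideogram coordinates, adequate for
# band-level breakpoint placement only. 0-based half-open.
chrom	start	end	band
1	0	11045455	p36
1	11045455	22090909	p35
1	22090909	33136364	p34
1	33136364	44181818	p33
1	44181818	55227273	p32
1	55227273	66272727	p31
1	66272727	77318182	p22
1	77318182	88363636	p21
1	88363636	99409091	p13
1	99409091	110454545	p12
1	110454545	121500000	p11
1	128900000	138157740	q11
1	138157740	147415480	q12
1	147415480	156673220	q21
1	156673220	165930960	q22
1	165930960	175188700	q23
1	175188700	184446440	q24
1	184446440	193704181	q25
1	193704181	202961921	q31
1	202961921	212219661	q32
1	212219661	221477401	q41
1	221477401	230735141	q42
1	230735141	239992881	q43
1	239992881	249250621	q44
2	0	8227273	p25
2	8227273	16454545	p24
2	16454545	24681818	p23
2	24681818	32909091	p22
2	32909091	41136364	p21
2	41136364	49363636	p16
2	49363636	57590909	p15
2	57590909	65818182	p14
2	65818182	74045455	p13
2	74045455	82272727	p12
2	82272727	90500000	p11
2	96800000	106559958	q11
2	106559958	116319916	q12
2	116319916	126079875	q13
2	126079875	135839833	q14
2	135839833	145599791	q21
2	145599791	155359749	q22
2	155359749	165119707	q23
2	165119707	174879666	q24
2	174879666	184639624	q31
2	184639624	194399582	q32
2	194399582	204159540	q33
2	204159540	213919498	q34
2	213919498	223679457	q35
2	223679457	233439415	q36
2	233439415	243199373	q37
3	0	8790000	p26
3	8790000	17580000	p25
3	17580000	26370000	p24
3	26370000	35160000	p23
3	35160000	43950000	p22
3	43950000	52740000	p21
3	52740000	61530000	p14
3	61530000	70320000	p13
3	70320000	79110000	p12
3	79110000	87900000	p11
3	93900000	102576869	q11
3	102576869	111253738	q12
3	111253738	119930608	q13
3	119930608	128607477	q21
3	128607477	137284346	q22
3	137284346	145961215	q23
3	145961215	154638084	q24
3	154638084	163314953	q25
3	163314953	171991822	q26
3	171991822	180668692	q27
3	180668692	189345561	q28
3	189345561	198022430	q29
4	0	8033333	p16
4	8033333	16066667	p15
4	16066667	24100000	p14
4	24100000	32133333	p13
4	32133333	40166667	p12
4	40166667	48200000	p11
4	52700000	61353392	q11
4	61353392	70006784	q12
4	70006784	78660177	q13
4	78660177	87313569	q21
4	87313569	95966961	q22
4	95966961	104620354	q23
4	104620354	113273746	q24
4	113273746	121927138	q25
4	121927138	130580530	q26
4	130580530	139233922	q27
4	139233922	147887315	q28
4	147887315	156540707	q31
4	156540707	165194099	q32
4	165194099	173847492	q33
4	173847492	182500884	q34
4	182500884	191154276	q35
5	0	9220000	p15
5	9220000	18440000	p14
5	18440000	27660000	p13
5	27660000	36880000	p12
5	36880000	46100000	p11
5	50700000	60716558	q11
5	60716558	70733117	q12
5	70733117	80749675	q13
5	80749675	90766234	q14
5	90766234	100782792	q15
5	100782792	110799351	q21
5	110799351	120815909	q22
5	120815909	130832468	q23
5	130832468	140849026	q31
5	140849026	150865585	q32
5	150865585	160882143	q33
5	160882143	170898702	q34
5	170898702	180915260	q35
6	0	8385714	p25
6	8385714	16771429	p24
6	16771429	25157143	p23
6	25157143	33542857	p22
6	33542857	41928571	p21
6	41928571	50314286	p12
6	50314286	58700000	p11
6	63300000	71593467	q11
6	71593467	79886933	q12
6	79886933	88180400	q13
6	88180400	96473867	q14
6	96473867	104767333	q15
6	104767333	113060800	q16
6	113060800	121354267	q21
6	121354267	129647734	q22
6	129647734	137941200	q23
6	137941200	146234667	q24
6	146234667	154528134	q25
6	154528134	162821600	q26
6	162821600	171115067	q27
7	0	8285714	p22
7	8285714	16571429	p21
7	16571429	24857143	p15
7	24857143	33142857	p14
7	33142857	41428571	p13
7	41428571	49714286	p12
7	49714286	58000000	p11
7	61700000	72526518	q11
7	72526518	83353036	q21
7	83353036	94179554	q22
7	94179554	105006072	q31
7	105006072	115832591	q32
7	115832591	126659109	q33
7	126659109	137485627	q34
7	137485627	148312145	q35
7	148312145	159138663	q36
8	0	8620000	p23
8	8620000	17240000	p22
8	17240000	25860000	p21
8	25860000	34480000	p12
8	34480000	43100000	p11
8	48100000	62137717	q11
8	62137717	76175435	q12
8	76175435	90213152	q13
8	90213152	104250870	q21
8	104250870	118288587	q22
8	118288587	132326305	q23
8	132326305	146364022	q24
9	0	6757143	p24
9	6757143	13514286	p23
9	13514286	20271429	p22
9	20271429	27028571	p21
9	27028571	33785714	p13
9	33785714	40542857	p12
9	40542857	47300000	p11
9	50700000	60757048	q11
9	60757048	70814096	q12
9	70814096	80871144	q13
9	80871144	90928192	q21
9	90928192	100985239	q22
9	100985239	111042287	q31
9	111042287	121099335	q32
9	121099335	131156383	q33
9	131156383	141213431	q34
10	0	7600000	p15
10	7600000	15200000	p14
10	15200000	22800000	p13
10	22800000	30400000	p12
10	30400000	38000000	p11
10	42300000	55619250	q11
10	55619250	68938499	q21
10	68938499	82257749	q22
10	82257749	95576998	q23
10	95576998	108896248	q24
10	108896248	122215497	q25
10	122215497	135534747	q26
11	0	10320000	p15
11	10320000	20640000	p14
11	20640000	30960000	p13
11	30960000	41280000	p12
11	41280000	51600000	p11
11	55700000	64511835	q11
11	64511835	73323670	q12
11	73323670	82135505	q13
11	82135505	90947340	q14
11	90947340	99759176	q21
11	99759176	108571011	q22
11	108571011	117382846	q23
11	117382846	126194681	q24
11	126194681	135006516	q25
12	0	11100000	p13
12	11100000	22200000	p12
12	22200000	33300000	p11
12	38200000	48827988	q11
12	48827988	59455977	q12
12	59455977	70083965	q13
12	70083965	80711953	q14
12	80711953	91339942	q15
12	91339942	101967930	q21
12	101967930	112595918	q22
12	112595918	123223907	q23
12	123223907	133851895	q24
13	0	5433333	p13
13	5433333	10866667	p12
13	10866667	16300000	p11
13	19500000	29066988	q11
13	29066988	38633976	q12
13	38633976	48200963	q13
13	48200963	57767951	q14
13	57767951	67334939	q21
13	67334939	76901927	q22
13	76901927	86468915	q31
13	86468915	96035902	q32
13	96035902	105602890	q33
13	105602890	115169878	q34
14	0	5366667	p13
14	5366667	10733333	p12
14	10733333	16100000	p11
14	19100000	28905504	q11
14	28905504	38711009	q12
14	38711009	48516513	q13
14	48516513	58322018	q21
14	58322018	68127522	q22
14	68127522	77933027	q23
14	77933027	87738531	q24
14	87738531	97544036	q31
14	97544036	107349540	q32
15	0	5266667	p13
15	5266667	10533333	p12
15	10533333	15800000	p11
15	20700000	28139217	q11
15	28139217	35578435	q12
15	35578435	43017652	q13
15	43017652	50456870	q14
15	50456870	57896087	q15
15	57896087	65335305	q21
15	65335305	72774522	q22
15	72774522	80213740	q23
15	80213740	87652957	q24
15	87652957	95092175	q25
15	95092175	102531392	q26
16	0	11533333	p13
16	11533333	23066667	p12
16	23066667	34600000	p11
16	38600000	45993536	q11
16	45993536	53387072	q12
16	53387072	60780608	q13
16	60780608	68174145	q21
16	68174145	75567681	q22
16	75567681	82961217	q23
16	82961217	90354753	q24
17	0	7400000	p13
17	7400000	14800000	p12
17	14800000	22200000	p11
17	25800000	33713601	q11
17	33713601	41627203	q12
17	41627203	49540804	q21
17	49540804	57454406	q22
17	57454406	65368007	q23
17	65368007	73281609	q24
17	73281609	81195210	q25
18	0	15400000	p11
18	19000000	30815450	q11
18	30815450	42630899	q12
18	42630899	54446349	q21
18	54446349	66261798	q22
18	66261798	78077248	q23
19	0	8133333	p13
19	8133333	16266667	p12
19	16266667	24400000	p11
19	28600000	38776328	q11
19	38776328	48952655	q12
19	48952655	59128983	q13
20	0	8533333	p13
20	8533333	17066667	p12
20	17066667	25600000	p11
20	29400000	40608507	q11
20	40608507	51817013	q12
20	51817013	63025520	q13
21	0	3633333	p13
21	3633333	7266667	p12
21	7266667	10900000	p11
21	14300000	25576632	q11
21	25576632	36853263	q21
21	36853263	48129895	q22
22	0	4066667	p13
22	4066667	8133333	p12
22	8133333	12200000	p11
22	17900000	29034855	q11
22	29034855	40169711	q12
22	40169711	51304566	q13
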