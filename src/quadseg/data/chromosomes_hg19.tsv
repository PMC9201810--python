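# hg19-derived autosome table; coordinates 0-based half-open;
# centromere (acen) intervals approximate.
chrom	length	cen_start	cen_end
1	249250621	121500000	128900000
2	243199373	90500000	96800000
3	198022430	87900000	93900000
4	191154276	48200000	52700000
5	180915260	46100000	50700000
6	171115067	58700000	63300000
7	159138663	58000000	61700000
8	146364022	43100000	48100000
9	141213431	47300000	50700000
10	135534747	38000000	42300000
11	135006516	51600000	55700000
12	133851895	33300000	38200000
13	115169878	16300000	19500000
14	107349540	16100000	19100000
15	102531392	15800000	20700000
16	90354753	34600000	38600000
17	81195210	22200000	25800000
18	78077248	15400000	19000000
19	59128983	24400000	28600000
20	63025520	25600000	29400000
21	48129895	10900000	14300000
22	51304566	12200000	17900000
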