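chrom	total_mb	missing_mb	n_cgi	density_assayed	mean_density	sd_density	skew_density
1	249.3	24.0	3430	15.2	15.1	16.0	4.3
2	243.2	5.0	2553	10.7	10.8	9.5	1.8
3	198.0	3.2	1814	9.3	9.3	8.1	2.0
4	191.2	3.5	1664	8.9	9.0	11.8	4.9
5	180.9	3.2	1884	10.6	10.6	13.8	4.0
6	171.1	3.7	1954	11.7	12.0	12.0	2.1
7	159.1	3.8	2256	14.5	14.7	19.2	3.3
8	146.4	3.5	1562	10.9	10.9	14.2	4.0
9	141.2	21.1	1814	15.1	14.7	15.3	3.2
10	135.5	4.2	1733	13.2	12.6	13.5	4.4
11	135.0	3.9	1776	13.5	13.9	14.8	2.8
12	133.9	3.4	1832	14.0	13.7	13.6	2.1
13	115.2	19.6	959	10.0	10.3	14.4	4.2
14	107.3	19.1	1180	13.4	13.2	13.0	2.3
15	102.5	20.8	1187	14.5	14.2	9.3	0.9
16	90.4	11.5	1894	24.0	23.5	28.5	2.3
17	81.2	3.4	2210	28.4	28.0	22.3	1.4
18	78.1	3.4	805	10.8	11.2	15.0	4.8
19	59.1	3.3	3147	56.4	55.9	40.6	1.6
20	63.0	3.5	1111	18.7	18.5	20.5	3.2
21	48.1	13.0	502	14.3	13.1	16.2	2.0
22	51.3	16.4	976	28.0	26.6	17.8	1.2
X	155.3	4.2	1541	10.2	10.5	12.6	3.7
Y	59.4	33.7	311	12.1	11.3	20.6	3.4
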