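0	ATCATGCC
1	CTCGATCA
2	GCTCTTCT
3	AGTGGGAT
4	ACTCTCTG
5	AATCTGCG
6	ACTCACGT
7	CTTCCAAC
8	GCTTCTAG
9	TAGGAGGT
10	GATCGACT
11	TAACGCTG
12	TAAGCGGA
13	CTGTGATC
14	CCCTAATC
15	TGGAAGGA
16	TACTACCG
17	CTTATGGG
18	TCAGCAAG
19	CGACTTCT
20	AGTGTCGA
21	TGCGATTC
22	CAACGACA
23	GATCTGTC
24	GCCAACTA
25	ATGAGGGA
26	TAGAACGG
27	CCGTAACA
28	TAGACTGC
29	GCTGGATT
30	GTGAGTCA
31	TCATGGAC
32	ACCACTAC
33	TCCTAAGG
34	GGCTAAAG
35	CCAACTGA
36	TCGTCTTG
37	TTGGGAAC
38	AATAGCCC
39	CTGTCGAA
40	CCCCATAT
41	AACCTCTC
42	GGTTTACG
43	GCAGAAGA
44	TAGAGGAG
45	GAAAGGGA
46	ATCGACGA
47	GCAAGTAC
48	TCAGACAC
49	CTTGGTTG
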