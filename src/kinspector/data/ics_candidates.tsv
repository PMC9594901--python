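ics_id	guide_used	n_reads	founder	chrom	start	end	region	gene
1	right	1820	-	chr2	164954903	164955063	on_target	Mmp9
2	left	1680	-	chr2	164954709	164955052	on_target	Mmp9
3	right	269	6	chr2	43676988	43677099	intronic	Kynu
4	right	158	1	chr2	164958347	164958445	intergenic	-
5	right	74	7	chr2	27945902	27946004	intronic	Col5a1
6	right	51	-	chr10	8621100	8621200	intronic	Cnnm2
7	left	48	9	chr9	63264772	63264909	intronic	Map2k5
8	right	43	-	chr6	91473078	91473209	intronic	Chchd4
9	left	42	7	chr2	27947501	27947631	intronic	Col5a1
10	right	40	11	chr2	164951625	164951696	intronic	Mmp9
11	right	30	-	chr11	44994980	44995104	intronic	Ebf1
12	left	25	-	chr12	118243649	118243801	intronic	Sp4
13	right	23	-	chr15	86334151	86334255	intronic	Tbc1d22a
14	left	23	6	chr2	43677155	43677290	intronic	Kynu
15	right	21	11	chr2	164951440	164951518	intronic	Mmp9
16	right	20	-	chr17	10769843	10769900	intronic	Pacrg
17	right	20	-	chr17	61954898	61955001	intergenic	-
18	right	15	-	chr10	107374530	107374593	intronic	Lin7a
19	left	15	-	chr6	38606367	38606454	exonic/intronic	Luc7l2
20	right	12	-	chr18	43026996	43027098	intronic	Ppp2r2b
21	right	10	-	chr2	164954849	164954903	on_target	Mmp9
22	right	8	-	chr1	88986042	88986123	intergenic	-
23	right	8	7	chr19	57114454	57114530	intronic	Ablim1
24	right	8	-	chr6	10123095	10123157	intergenic	-
25	left	7	-	chr5	32180060	32180151	intergenic	-
26	right	6	-	chr2	74223656	74223761	intergenic	-
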