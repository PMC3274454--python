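variant_id	alias	position	region_class	deleterious_class	ref	alt	case_minor	case_alleles	control_minor	control_alleles	fisher_p	is_novel
Novel_1	c.-597C>T	78391506	promoter	NA	C	T	0	1312	1	745	0.363	1
Novel_2	c.-458G>A	78391367	promoter	NA	G	A	1	1309	0	746	1.000	1
Novel_3	c.-261G>A	78391170	utr5	NA	G	A	1	1309	0	746	1.000	1
Novel_4	c.-233C>T	78391142	utr5	NA	C	T	4	1306	0	746	0.303	1
Novel_5	c.-232G>A	78391141	utr5	NA	G	A	1	1311	0	746	1.000	1
Novel_6	c.-45G>C	78383664	utr5	NA	G	C	1	1349	0	746	1.000	1
Novel_7	c.-36A>G	78383655	utr5	NA	A	G	1	1349	0	746	1.000	1
Novel_8	c.-32G>A	78383651	utr5	NA	G	A	1	1349	0	746	1.000	1
Novel_9	T33T	78383521	coding_syn	NA	T	C	1	1349	0	746	1.000	1
Novel_10	R61Q	78383438	coding_nonsyn	possibly	G	A	2	1348	1	745	1.000	1
Novel_11	P73L	78383402	coding_nonsyn	probably	C	T	0	1350	1	745	0.357	1
Novel_12	T76I	78383393	coding_nonsyn	benign	C	T	0	1350	1	745	0.357	1
Novel_13	D99N	78383325	coding_nonsyn	probably	G	A	1	1349	1	745	1.000	1
Novel_14	E116E	78383272	coding_syn	NA	G	A	1	1349	0	746	1.000	1
Novel_15	A135E	78383216	coding_nonsyn	benign	C	A	0	1350	1	745	0.357	1
Novel_16	A142T	78383196	coding_nonsyn	possibly	G	A	1	1349	0	746	1.000	1
Novel_17	E241Q	78382899	coding_nonsyn	probably	G	C	1	1357	0	752	1.000	1
Novel_18	F246F	78382882	coding_syn	NA	T	C	0	1358	1	751	0.356	1
rs35283702	G277R	78382791	coding_nonsyn	probably	G	A	15	1343	7	745	0.825	0
Novel_19	H287Q	78382759	coding_nonsyn	possibly	C	G	1	1357	0	752	1.000	1
Novel_20	F377L	78382489	coding_nonsyn	benign	C	G	0	1374	1	763	0.359	1
rs34687659	Q392R	78382445	coding_nonsyn	possibly	A	G	0	1374	1	763	0.359	0
Novel_21	A407T	78382401	coding_nonsyn	probably	G	A	1	1373	0	764	1.000	1
Novel_22	P415P	78382375	coding_syn	NA	G	A	2	1372	2	762	0.622	1
Novel_23	D432H	78382326	coding_nonsyn	possibly	G	C	2	1372	0	764	0.540	1
Novel_24	V478I	78382188	coding_nonsyn	benign	G	A	0	1374	1	763	0.359	1
Novel_25	intron2_a	78382160	intron	NA	C	A	1	1373	0	764	1.000	1
Novel_26	intron2_b	78382155	intron	NA	A	C	1	1373	0	764	1.000	1
Novel_27	intron2_c	78382047	intron	NA	T	C	1	1373	0	764	1.000	1
rs35792712	P488P	78382015	coding_syn	NA	T	G	0	1374	1	763	0.359	0
Novel_28	G589R	78381714	coding_nonsyn	benign	G	C	1	1365	0	766	1.000	1
Novel_29	A657A	78381508	coding_syn	NA	G	A	1	1365	0	766	1.000	1
Novel_30	utr3_a	78381034	utr3	NA	G	A	1	1357	0	756	1.000	1
Novel_31	utr3_b	78380851	utr3	NA	A	G	1	1365	2	752	0.290	1
Novel_32	utr3_c	78380743	utr3	NA	A	G	2	1364	0	754	0.541	1
Novel_33	utr3_d	78380697	utr3	NA	T	G	1	1365	0	754	1.000	1
Novel_34	downstream_a	78380590	downstream	NA	T	C	2	1318	1	751	1.000	1
Novel_35	downstream_b	78380548	downstream	NA	G	A	17	1305	9	743	1.000	1
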