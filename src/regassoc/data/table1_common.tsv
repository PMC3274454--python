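variant_id	position	region_class	deleterious_class	ref	alt	f_case	f_control	fisher_p	is_novel
rs3744165	78383731	utr5	NA	C	A	0.171	0.161	0.541	0
rs12450046	78383677	utr5	NA	C	T	0.186	0.172	0.478	0
rs8074277	78382917	coding_nonsyn	benign	A	G	0.189	0.180	0.640	0
rs35653278	78382757	coding_nonsyn	probably	C	T	0.092	0.090	0.937	0
rs34188981	78382558	coding_syn	NA	C	T	0.021	0.021	1.000	0
rs12948179	78381781	coding_syn	NA	T	C	0.393	0.420	0.233	0
rs12938126	78381754	coding_syn	NA	A	G	0.392	0.420	0.232	0
rs71918228	78381176	utr3	NA	CAAA	-	0.465	0.478	0.586	0
rs35156590	78380584	downstream	NA	-	T	0.369	0.418	0.028	0
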