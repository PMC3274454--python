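haplotype	hap_freq	f_case	f_control	p_value	emp_p	odds_ratio	or_low	or_high
CCACCCGT	0.374	0.354	0.410	0.0106	0.0311	0.79	0.66	0.94
CCACCTA-	0.246	0.253	0.234	0.3321	0.9359	NA	NA	NA
ACACCTA-	0.137	0.138	0.136	0.9158	1.0000	NA	NA	NA
CTGCCTA-	0.089	0.091	0.085	0.6426	0.9995	NA	NA	NA
CTGTCTA-	0.089	0.091	0.086	0.7198	0.9997	NA	NA	NA
ACACTTA-	0.020	0.020	0.020	0.9666	1.0000	NA	NA	NA
CCACCCG-	0.019	0.026	0.006	0.0011	0.0024	3.70	1.45	9.46
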