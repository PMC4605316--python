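srna_id	gene_id	reported_pcc
rsRNA-1336	FOXO3	-0.62
rsRNA-3091	EMP2	-0.77
rsRNA-3790	TAF8	-0.56
rsRNA-5402	ATM	-0.96
rsRNA-7906	EMP2	-0.91
rsRNA-8294	E2F8	-0.96
rsRNA-9338	TERF1	-0.98
rsRNA-9345	BRCA2	-0.78
rsRNA-3091	TAF8	-0.66
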