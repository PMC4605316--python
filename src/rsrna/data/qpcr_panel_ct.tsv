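entity	A549	MDA-MB-231	HeLa	MCF7
rsRNA-1336	32.48	32.46	31.41	29.43
FOXO3	23.17	25.73	25.07	26.21
rsRNA-3091	24.17	24.81	23.19	21.66
EMP2	20.80	23.90	29.22	29.26
rsRNA-3790	26.82	27.60	26.55	25.02
TAF8	19.94	22.89	23.08	24.71
rsRNA-5402	31.20	32.02	29.52	28.50
ATM	24.48	22.24	26.22	NA
rsRNA-7906	34.15	34.53	31.96	31.4
rsRNA-8294	25.20	25.77	24.79	23.11
E2F8	22.42	20.73	21.61	28.62
rsRNA-9338	32.28	33.55	31.82	29.70
TERF1	26.46	25.66	26.31	27.32
rsRNA-9345	35	35	34.03	32.16
BRCA2	22.76	26.78	33.01	33.18
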