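# Per-chromosome counts of high/low variant-frequency regions (100-kb
# windows, 50-kb step, coverage-corrected), transcribed from the published
# region-count table with its printed totals row.
Chr	SNP_high	SNP_low	InDel_high	InDel_low	SV_high	SV_low
Chr01	0	64	3	20	3	72
Chr02	6	13	19	9	8	49
Chr03	0	32	15	16	3	93
Chr04	3	32	2	5	3	71
Chr05	8	16	19	13	10	28
Chr06	5	32	6	11	4	65
Chr07	10	27	13	19	1	60
Chr08	1	14	2	6	2	23
Chr09	4	17	4	1	0	22
Chr10	1	12	4	2	2	17
Chr11	2	23	0	18	0	42
Chr12	7	10	4	4	3	29
Total	47	292	91	124	39	571
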