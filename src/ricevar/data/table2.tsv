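# Per-chromosome SNP/InDel/SV counts of the focal line against its
# reference, transcribed from the published summary table; the Total row
# holds the genome-wide totals as printed in the text.
Chr	SNP	InDel	SV
Chr01	39674	8046	483
Chr02	36901	7199	231
Chr03	32756	6451	327
Chr04	27159	4810	282
Chr05	26229	4951	236
Chr06	24092	4424	225
Chr07	21525	3699	118
Chr08	27935	5200	421
Chr09	13531	2524	114
Chr10	22382	3826	253
Chr11	13777	2490	193
Chr12	21666	3752	213
Total	307627	57372	3096
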