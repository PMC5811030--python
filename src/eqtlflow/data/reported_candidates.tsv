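variant_id	gene_id	candidate_genotype	mean_ebv	fdr_ebv	tissue	overlapping_trait
rs81342651	BAIAP2	CC	-0.732	0.029	liver	Fat androstenone level
rs81265837	ARMC7	AA	-0.696	0.000	both	Fat androstenone level
rs81435284	ARMC7	AA	-0.696	0.000	both	Fat androstenone level
rs81441228	EPHA3	GG	-0.412	0.040	testis	Fat androstenone level
rs80817135	KALRN	CC	-0.805	0.045	testis	Fat androstenone level
rs81448091	ENSSSCG00000029252	AA	-0.805	0.048	testis	Fat androstenone level
rs81357053	BBOX1	AA	-0.412	0.044	liver	Fat androstenone level
rs81305789	BBOX1	AA	-0.412	0.044	liver	Fat androstenone level
rs81340851	NAALADL1	TC	-0.412	0.045	liver	Fat androstenone level
rs81212188	NAALADL1	AG	-0.412	0.045	liver	Fat androstenone level
rs81359616	NAALADL1	TC	-0.412	0.045	liver	Fat androstenone level
rs81309447	ATP13A3	AG	-0.248	0.020	liver	Off-Flavor Score
rs81478384	ATP13A3	TT	-0.805	0.020	liver	Off-Flavor Score
rs81303987	ATP13A3	AC	-0.248	0.020	liver	Off-Flavor Score
rs80803537	PLCD1	AG	-0.499	0.042	liver	Off-Flavor Score
rs81448091	ENSSSCG00000011817	AA	-0.805	0.048	testis	Off-Flavor Score
rs80919384	ENSSSCG00000024047	TC	-0.412	0.028	liver	Off-Flavor Score
rs337275357	ENSSSCG00000024047	AG	-0.412	0.028	liver	Off-Flavor Score
rs81433762	TEN1	AA	-0.805	0.006	liver	Overall impression, sensory panel
rs81434107	TEN1	AA	-0.805	0.006	liver	Overall impression, sensory panel
rs81311681	HEXDC	TT	-0.768	0.013	liver	Overall impression, sensory panel
rs81293055	ENSSSCG00000004117	AG	-0.294	0.025	testis	indole, laboratory
rs80806865	ENSSSCG00000004117	AG	-0.294	0.025	testis	indole, laboratory
rs81305046	BAIAP2	AA	-0.412	0.002	liver	indole, laboratory
rs81438833	BAIAP2	CC	-0.412	0.002	liver	indole, laboratory
rs81439307	BAIAP2	CC	-0.412	0.002	liver	indole, laboratory
rs81440749	BAIAP2	GG	-0.412	0.002	liver	indole, laboratory
rs81434341	HEXDC	AA	-0.768	0.013	liver	indole, laboratory
rs81271924	HEXDC	TT	-0.768	0.013	liver	indole, laboratory
rs81283210	HEXDC	AA	-0.768	0.017	liver	indole, laboratory
rs81233143	INTS2	TT	-0.412	0.018	liver	indole, laboratory
rs327709564	AOC2	AG	-0.294	0.028	liver	indole, laboratory
rs80864895	HEXDC	GG	-0.732	0.029	liver	indole, laboratory
rs81238764	MAPT	AG	-0.412	0.029	liver	indole, laboratory
rs80864895	BAIAP2	GG	-0.732	0.029	liver	indole, laboratory
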