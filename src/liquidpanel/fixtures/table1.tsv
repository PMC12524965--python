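sample	material	vaf_percent	gene	chrom_location	base_change	protein_change	cosmic_id	sift_call	sift_score	polyphen_call	polyphen_score	revel_score	consequence
ctD4	ctDNA_blood	2.85	ALK	chr2 (p23.2)	c.(3824G>A)	p.(R1275Q)	COSV66555567	Del	0	PRD	1	0.885	missense
ctD4	ctDNA_blood	28.5	ALK	chr2 (p23.2)	c.(3522C>A)	p.(F1174L)	COSV66556325	Del	0.03	POD	0.641	0.752	missense
ctD10	ctDNA_blood	1.38	ALK	chr2 (p23.2)	c.(3509T>A)	p.(I1170N)	COSV66589132	Del	0	PRD	1	0.906	missense
ctD10	ctDNA_blood	26.16	KRAS	chr12 (p12.1)	c.(35G>T)	p.(G12V)	COSV55497419	Del	0	PRD	0.972	0.91	missense
ctD10	ctDNA_blood	3.61	PTPN11	chr12 (q24.13)	c.(179G>C)	p.(G60A)	COSV61006397	Del	0.01	PRD	0.953	0.907	missense
ctD11	ctDNA_blood	84.88	TP53	chr17 (p13.1)	c.(537T>A)	p.(H179G)	COSV52673406	Del	0	PRD	0.98	0.79	missense
gD1	germline	1.4	TP53	chr17 (p13.1)	c.(537T>A)	p.(H179Q)	COSV52669519	Del	0	PRD	0.98	0.79	missense
ctD13	ctDNA_blood	3.33	ALK	chr2 (p23.2)	c.(3522C>A)	p.(F1174L)	COSV66556325	Del	0.03	POD	0.641	0.752	missense
ctD15	ctDNA_blood	35.8	PTPN11	chr12 (q24.13)	c.(922A>G)	p.(N308D)	COSV61006575	Del	0.03	B	0.134	0.838	missense
gD2	germline	43.9	PTPN11	chr12 (q24.13)	c.(922A>G)	p.(N308D)	COSV61006575	Del	0.03	B	0.134	0.838	missense
ctD16	ctDNA_blood	4.34	PTPN11	chr12 (q24.13)	c.(181G>T)	p.(D61Y)	COSV61004841	Del	0	PRD	0.997	0.933	missense
ctD17	ctDNA_blood	2.26	NRAS	chr1 (p13.2)	c.(181C>A)	p.(Q61K)	COSV54736310	Del	0.01	POD	0.709	N/A	missense
ctD20	ctDNA_blood	91.64	TP53	chr17 (p13.1)	c.(840A>T)	p.(R280S)	COSV52782181	Del	0.03	POD	0.843	0.878	missense
ctD21	ctDNA_blood	83.4	TP53	chr17 (p13.1)	c.(840A>T)	p.(R280S)	COSV52801834	Del	0.03	POD	0.843	0.878	missense
ctD22	ctDNA_blood	29.03	ALK	chr2 (p23.2)	c.(3824G>A)	p.(R1275Q)	COSV66555567	Del	0	PRD	1	0.885	missense
ctD25	ctDNA_blood	18.7	PTPN11	chr12 (q24.13)	c.(226G>C)	p.(E76Q)	COSV61004751	Del	0.01	PRD	0.979	0.733	missense
ctD28	ctDNA_blood	2.2	CREBBP	chr16 (p13.3)	c.(4478T>A)	p.(I1493K)	COSV52129182	Del	0	PRD	0.991	0.929	missense
1	cell_line	44.4	KRAS	chr12 (p12.1)	c.(35G>T)	p.(G12V)	COSV55497419	Del	0	PRD	0.972	0.91	missense
1	cell_line	50.9	SMARCA4	chr19 (p13.2)	c.(2917C>T)	p.(R973W)	COSV60787034	Del	0	PRD	1	0.86	missense
1	cell_line	49.6	ALK	chr2 (p23.2)	c.(3522C>A)	p.(F1174L)	COSV66555460	Del	0.03	POD	0.641	0.752	missense
2	cell_line	99.1	TP53	chr17 (p13.1)	c.(404G>T)	p.(C135F)	COSV52680475	Del	0	PRD	1	0.96	missense
2	cell_line	100	NF1	chr17 (q11.2)	c.(1989_2001del)	p.(G663fs)	N/A	N/A	N/A	N/A	N/A	N/A	splice_donor
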