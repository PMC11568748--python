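decipher_id	age_years	sex	n_hpo_terms	gene1	gene2	pair_score	score_g1	score_g2	n_attr_g1	n_attr_g2	n_attr_both	n_attr_neither	n_excluded
258830	11.0	female	18	TCF12	CDK13	0.800	0.733	0.616	0	5	12	0	1
271137	11.0	male	9	MBD5	CHD2	0.743	0.686	0.672	1	0	7	0	1
291190	13.0	female	7	SHANK2	PPP2R5D	0.698	0.494	0.452	0	4	3	0	0
291341	10.0	female	6	ZC4H2	SYNGAP1	0.619	0.146	0.143	3	1	2	0	0
303270	19.0	female	6	NF1	CBL	0.619	0.621	0.611	0	0	6	0	0
270803	9.3	female	10	BPTF	QRICH1	0.615	0.525	0.451	2	0	8	0	0
261175	7.8	male	9	FLNA	ZBTB20	0.603	0.450	0.373	1	0	8	0	0
299681	4.5	male	2	YWHAG	STAG1	0.600	0.673	0.494	0	0	2	0	0
307458	2.1	male	4	TAOK1	SLC6A1	0.594	0.737	0.441	0	0	3	0	1
300981	2.3	male	10	DNMT3A	PTEN	0.593	0.553	0.502	1	0	6	0	3
286914	6.8	male	6	POU3F3	EHMT1	0.588	0.581	0.440	0	1	4	0	1
271406	7.2	male	2	IQSEC2	SMC1A	0.584	0.589	0.425	0	0	2	0	0
272920	3.8	male	3	IQSEC2	SMC1A	0.584	0.688	0.535	0	0	3	0	0
272921	8.4	male	1	IQSEC2	SMC1A	0.584	0.536	0.298	0	0	1	0	0
272922	9.9	male	2	IQSEC2	SMC1A	0.584	0.472	0.243	0	0	2	0	0
300851	0.8	male	6	PPP2R5D	FGFR3	0.583	0.554	0.495	1	0	5	0	0
295136	1.3	female	3	EEF1A2	NF1	0.579	0.404	0.331	0	1	1	1	0
266333	1.7	female	7	SMARCA4	ANKRD11	0.577	0.514	0.421	1	1	4	0	1
293170	3.1	male	2	KIDINS220	CC2D2A	0.572	0.610	0.593	0	1	1	0	0
276438	8.3	female	5	NAA15	CHD3	0.569	0.474	0.398	1	0	3	0	1
273503	11.0	male	6	TAOK1	ZEB2	0.551	0.731	0.445	2	2	2	0	0
278939	3.4	male	11	PACS1	RAD21	0.548	0.547	0.444	1	2	7	0	1
280956	12.0	female	11	NFIX	SMARCA2	0.545	0.476	0.386	1	2	7	1	0
271955	2.4	male	6	SCN2A	TBL1XR1	0.542	0.501	0.337	0	3	3	0	0
265387	5.6	male	7	CTCF	FBN2	0.529	0.493	0.212	4	0	3	0	0
300478	2.3	male	8	PBX1	RAF1	0.515	0.732	0.373	0	0	8	0	0
290989	4.1	male	21	GNB2	NAA15	0.497	0.763	0.538	2	4	11	0	4
264530	7.3	male	4	ATRX	SETD5	0.495	0.486	0.352	0	1	3	0	0
281373	22.0	female	7	NAA15	PRMT7	0.473	0.699	0.381	0	3	4	0	0
264597	10.0	female	14	ANKRD11	PDHA1	0.463	0.507	0.405	2	2	10	0	0
307561	7.5	male	6	ATRX	MED13	0.461	0.411	0.363	2	0	4	0	0
275085	16.0	male	21	ADNP	EBF3	0.454	0.464	0.356	5	0	16	0	0
306054	3.5	female	4	COL1A1	IQSEC2	0.446	0.541	0.407	2	0	2	0	0
269481	5.5	male	4	OPHN1	HSPG2	0.443	0.510	0.276	1	0	3	0	0
305998	6.4	male	11	GRIN2A	SETD5	0.441	0.547	0.538	1	7	3	0	0
272998	16.0	female	10	SLC13A5	SETD5	0.439	0.690	0.538	1	3	5	1	0
271765	2.9	male	7	MED13L	DMD	0.437	0.436	0.189	4	0	2	0	1
271952	8.3	female	6	PTEN	SIN3A	0.424	0.449	0.357	0	0	6	0	0
283972	20.0	female	12	POLR1C	SAMHD1	0.406	0.738	0.163	2	0	10	0	0
304477	16.0	female	11	HDAC8	PAX8	0.393	0.460	0.367	7	1	0	1	2
305580	6.4	female	8	WDFY3	MAN1B1	0.392	0.379	0.234	2	3	1	0	2
278908	9.5	male	5	TRIP12	CDK13	0.391	0.691	0.530	0	1	4	0	0
276430	2.6	male	4	NRXN1	ASH1L	0.379	0.461	0.218	0	1	3	0	0
280286	13.0	male	5	KMT2E	TAB2	0.358	0.395	0.370	2	0	2	1	0
259242	8.4	male	5	PTCHD1	COL1A1	0.334	0.768	0.340	2	1	1	0	1
264155	13.0	female	6	NF1	ITPR1	0.311	0.447	0.239	4	1	1	0	0
269952	6.8	female	7	SRCAP	DCX	0.305	0.309	0.307	3	1	3	0	0
260920	9.2	female	6	SOX11	TRIP12	0.294	0.504	0.353	1	0	5	0	0
264822	6.3	female	10	MYCN	SETD1B	0.294	0.364	0.347	1	3	6	0	0
286794	1.4	male	3	SHH	STS	0.290	0.610	0.061	2	0	1	0	0
265526	10.0	male	3	ARMC9	BRIP1	0.285	0.374	0.257	2	0	1	0	0
304171	1.8	male	6	PTPN11	NRXN1	0.256	0.391	0.202	3	0	3	0	0
266071	10.0	male	7	TCF20	STS	0.251	0.556	0.282	3	1	3	0	0
301569	4.7	male	10	TBX4	DYNC1H1	0.249	0.394	0.318	1	6	3	0	0
304140	5.3	male	4	NGLY1	COL4A3	0.249	0.619	0.172	1	1	1	0	1
284672	8.6	female	14	NEB	LZTR1	0.246	0.425	0.005	1	5	8	0	0
281387	1.3	male	11	AIPL1	FGFR3	0.223	0.514	0.505	4	7	0	0	0
269970	2.4	female	9	SLC6A1	TNFRSF13B	0.213	0.454	0.492	5	2	0	2	0
269973	2.4	female	8	SLC6A1	TNFRSF13B	0.213	0.526	0.413	5	1	0	2	0
276436	11.0	male	12	SYN1	SLC4A1	0.134	0.813	0.105	4	2	0	3	3
293597	10.0	female	6	SPATA5	TSHR	0.082	0.714	0.086	3	0	2	0	1
306313	13.0	female	12	SETD5	COL4A3	0.070	0.445	0.078	9	0	2	1	0
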