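patient	sample	source	gene	variant_type	cdna_change	protein_change	mutant_reads	ref_reads	printed_af	origin	bidirectional	loh	functional_class	validation	notes
P1	S1		TENM2	missense	c.6241G>A	p.D2081N	36	119	0.232	somatic			low	WGS	
P1	S1		B3GALT5	missense	c.673G>A	p.V225M	19	111	0.146	somatic			medium	WGS	
P1	S1		MAZ	missense	c.1148C>T	p.A383V	6	7	0.462	somatic			neutral	WGS	
P1	S1		GZF1	missense	c.1021G>A	p.G341S	23	84	0.215	somatic			low	RNA-seq	
P1	S2		TENM2	missense	c.6241G>A	p.D2081N	15	29	0.341	somatic			low	seen in S1	
P1	S2		B3GALT5	missense	c.673G>A	p.V225M	60	145	0.293	somatic			medium	seen in S1	
P1	S2		MAZ	missense	c.1148C>T	p.A383V			not seen	somatic			neutral	no coverage	
P1	S2		GZF1	missense	c.1021G>A	p.G341S	30	85	0.261	somatic			low	RNA-seq	
P3	S4		ATP7B	missense	c.2173A>T	p.R725W	40	59	0.404	somatic			medium	Sanger	
P3	S4		GPT2	nonsense	c.274C>T	p.R92*	46	69	0.400	somatic			NA	Sanger	
P4	S5		DBC1	missense	c.446G>A	p.R149H	11	29	0.275	somatic			neutral	RNA-seq	
P4	S5		LSS	missense	c.1010C>T	p.P337L	31	62	0.333	somatic			high	RNA-seq	
P4	S5		DSTYK	missense	c.865A>G	p.I289V	12	22	0.353	somatic			medium	RNA-seq	
P4	S5		MCLN2	missense	c.596C>G	p.S199C	3	22	0.120	somatic			medium	RNA-seq	
P4	S5		DYNC1H1	missense	c.8635A>G	p.K2879E	4	71	0.053	somatic			medium	RNA-seq	
P5	S6		CNOT3	missense	c.38G>A	p.R13H	32	144	0.182	somatic			medium	RNA-seq	
P5	S6		KIAA1370	missense	c.832G>A	p.E278K	16	42	0.276	somatic			low	RNA-seq	
P5	S6		ABCB4	missense	c.2339G>A	p.G780D	40	104	0.278	somatic			high	RNA-seq	
P5	S6		VILL	missense	c.1879G>A	p.A627T	15	37	0.288	somatic			neutral	RNA-seq	
P5	S6		EFEMP1	missense	c.1279C>T	p.R427W	21	48	0.304	somatic			medium	RNA-seq	
P5	S6		TNK2	missense	c.804C>G	p.I268M	4	68	0.056	somatic			medium	RNA-seq	
P6	S7		SPEN	missense	c.5437G>A	p.A1813T	12	75	0.138	somatic			neutral	Sanger	
P6	S7		SNRPA	missense	c.718G>C	p.V240L	9	81	0.100	somatic			medium	RNA-seq	
P6	S7		SGOL2	missense	c.1433G>C	p.G478A	30	155	0.162	somatic			low	RNA-seq	
P6	S7		CNIH3	missense	c.400G>A	p.E134K	40	70	0.364	somatic			medium	RNA-seq	
P6	S7		GSK3B	splice	c.1195_splice	p.D399_splice	12	29	0.293	somatic			NA	RNA-seq	
P6	S7		ATP1A1	missense	c.1696C>T	p.P566S	16	183	0.080	somatic			low	RNA-seq	
P6	S7		THBS3	missense	c.1576G>C	p.D526H	9	94	0.087	somatic			medium	RNA-seq	
P6	S7		ZNF304	nonsense	c.688A>T	p.K230*	6	74	0.075	somatic			NA	RNA-seq	
P6	S7		SEL1L2	missense	c.511G>A	p.E171K	6	41	0.128	somatic			medium	RNA-seq	
P6	S7		ZNF592	missense	c.3158C>G	p.P1053R	10	112	0.082	somatic			neutral	RNA-seq	
P6	S7		THBS3	missense	c.1576G>C	p.D526H	9	94	0.087	somatic			medium	RNA-seq	
P6	S7		TRPM6	missense	c.3965C>T	p.T1322I	31	158	0.164	somatic			low	RNA-seq	
P13	S14		GIGYF1	missense	c.953G>T	p.G318V	17	58	0.227	somatic			neutral	Sanger	
P13	S14		NEUROD4	missense	c.704C>T	p.S235L	28	125	0.183	somatic			low	Sanger	
P13	S14		POLR3F	missense	c.321A>G	p.I107M	7	40	0.149	somatic			medium	Sanger	
P13	S15		TMPPE	frameshift_del	c.139_143delCAGCT	p.QL47fs	77	570	0.119	somatic			NA	Sanger	
P13	S15		KIAA0232	missense	c.1672A>G	p.M558V	160	660	0.195	somatic			low	Sanger	
P13	S15		ANK2	missense	c.7060C>T	p.R2354C	179	590	0.233	somatic			neutral	Sanger	
P13	S15		PHF1	missense	c.160G>T	p.V54L	147	518	0.221	somatic			low	Sanger	
P13	S15		UBE3D	missense	c.344G>T	p.G115V	118	571	0.171	somatic			medium	Sanger	
P13	S15		OR8G5	missense	c.931G>T	p.V311L	162	886	0.155	somatic			low	Sanger	
P13	S15		ANKRD35	missense	c.200C>A	p.T67K	58	603	0.088	somatic			neutral	SNaPshot	
P13	S15		ZNF804B	missense	c.643C>T	p.H215Y	48	799	0.057	somatic			medium	SNaPshot	
P13	S17		WWTR1	missense	c.317C>T	p.P106L	37	7	0.841	somatic			medium	Sanger	
P13	S17		NDUFA8	missense	c.284A>G	p.Q95R	294	53	0.847	somatic			low	Sanger	
P13	S17		GCAT	missense	c.1201G>T	p.G401W	69	9	0.885	somatic			high	Sanger	
P13	S17		ARHGAP35	missense	c.3818A>C	p.E1273A	68	19	0.782	somatic			high	Sanger	
P13	S17		CCDC132	missense	c.2460A>C	p.L820F	45	6	0.882	somatic			medium	Sanger	
P13	S18		MLKL	missense	c.553A>G	p.M185V	10	38	0.208	somatic			low	Sanger	
P13	S18		USH2A	missense	c.9638C>A	p.P3213Q	73	258	0.221	somatic			medium	Sanger	
P13	S18		CCDC39	missense	c.892C>T	p.R298C	29	60	0.326	somatic			NA	Sanger	
P13	S18		LIPA	missense	c.739G>A	p.V247I	33	216	0.133	somatic			neutral	Sanger	
P13	S18		ZNF821	missense	c.518C>G	p.S173W	54	155	0.258	somatic			low	Sanger	
P13	S18		MIER2	missense	c.1514C>T	p.S505L	46	200	0.187	somatic			low	Sanger	
P13	S18		GPR50	missense	c.1214A>G	p.K405R	22	218	0.092	somatic			low	SNaPshot	
P13	S18		TUBB2A	inframe_del	c.89_103delTCGACCCCACAGGCA	p.IDPTG30del	7	71	0.090	somatic			NA	Sanger	
P13	S20		ADAMTSL1	inframe_del	c.1387_1398delTGCATCGACCAT	p.CIDH463del	19	172	0.099	somatic			NA	Sanger	
P13	S20		ZSCAN21	inframe_del	c.1225_1239delCTCCACACCGGAGAG	p.LHTGE409del	10	93	0.097	somatic			NA	Sanger	
P13	S20		MAATS1	missense	c.743G>A	p.R248H	33	79	0.295	somatic			medium	Sanger	
P13	S20		NCF1	missense	c.568G>A	p.E190K	51	135	0.274	somatic			medium	Sanger	
P13	S21		UBE3D	frameshift_del	c.1130_1131delGC	p.R378fs	12	126	0.087	somatic			NA	SNaPshot	
P13	S23		KIAA1107	missense	c.334G>A	p.V112I	8	28	0.222	somatic			neutral	Sanger	
P13	S23		HOXD12	missense	c.491A>G	p.D164G	25	175	0.125	somatic			medium	Sanger	
P13	S23		BAP1	missense	c.1550C>T	p.T517M	23	160	0.126	somatic			low	Sanger	
P13	S23		TLL1	missense	c.1120C>T	p.H374Y	44	216	0.169	somatic			low	Sanger	
P13	S23		MAATS1	missense	c.743G>A	p.R248H	20	61	0.247	somatic			medium	Sanger	
P13	S23		NCF1	missense	c.568G>A	p.E190K	60	194	0.236	somatic			medium	Sanger	
P13	S23		ATP9A	missense	c.2813T>G	p.I938S	8	28	0.222	somatic			medium	SNaPshot	
P13	S24		ASPM	missense	c.2296C>T	p.R766C	97	261	0.271	somatic			medium	SNaPshot	
P13	S24		TRIP12	splice	c.5470-2A>G	p.L1824_splice	36	106	0.254	somatic			NA	Sanger	
P13	S24		MIS18BP1	missense	c.816C>A	p.S272R	54	108	0.333	somatic			low	Sanger	
P13	S24		ZNF578	frameshift_del	c.1414_1417delAGAC	p.RH472fs	27	85	0.241	somatic			NA	Sanger	
P13	S24		MAATS1	missense	c.743G>A	p.R248H	30	49	0.380	somatic			medium	Sanger	
P13	S24		NCF1	missense	c.568G>A	p.E190K	60	165	0.267	somatic			medium	Sanger	
P13	S24		ASPM	missense	c.247C>G	p.P83A	33	374	0.081	somatic			medium	Sanger	
P13	S26		WWC1	missense	c.2896C>T	p.R966C	51	94	0.352	somatic			medium	Sanger	
P13	S27		TRIP12	missense	c.4784G>A	p.R1595Q	19	69	0.216	somatic			high	Sanger	
P13	S27		WDR55	missense	c.790G>A	p.E264K	54	62	0.466	somatic			medium	Sanger	
P13	S27		LILRB5	missense	c.1291G>A	p.D431N	7	59	0.106	somatic			low	Sanger	
P13	S27		EXOC3	missense	c.1975A>G	p.I659V	12	150	0.074	somatic			low	SNaPshot	
P13	S29		PTPRF	missense	c.2269C>G	p.R757G	6	193	0.030	somatic			medium	Sanger	
P13	S29		PDE2A	missense	c.930C>A	p.D310E	22	159	0.122	somatic			medium	SNaPshot	
P13	S29		RNF24	missense	c.266A>G	p.D89G	69	141	0.329	somatic			low	Sanger	
P13	S29		GRM3	missense	c.2498A>G	p.N833S	15	174	0.079	somatic			medium	SNaPshot	
P13	S29		POLR2A	missense	c.2423C>G	p.P808R	15	198	0.070	somatic			high	SNaPshot	
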