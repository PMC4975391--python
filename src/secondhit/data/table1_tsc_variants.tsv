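patient	sample	source	gene	variant_type	cdna_change	protein_change	mutant_reads	ref_reads	printed_af	origin	bidirectional	loh	functional_class	validation	notes
P1	S1	abdominal LAM	TSC2	frameshift_del	c.2319delA	p.L773fs	49	41	0.54	somatic		Yes			WGS, RNA-Seq
P1	S2	chylous fluid cell cluster	TSC2	frameshift_del	c.2319delA	p.L773fs	5	8	0.39	somatic		Yes			
P2	S3	angiomyolipoma	TSC2	splice	c.976-15G>A	p.A326_splice	67	16	0.81	somatic		Yes			WGS, RNA-Seq, LAM
P3	S4	angiomyolipoma cell line	TSC2	frameshift_del	c.2250delC	p.L750fs	55	36	0.60	somatic		Yes			LAM
P4	S5	angiomyolipoma	TSC2	splice	c.4493+1G>A	p.S1498_splice	28	41	0.41	germline		2-hit			RNA-Seq, TSC
P4	S5	angiomyolipoma	TSC2	frameshift_del	c.4765delC	p.P1589fs	28	36	0.44	somatic					
P5	S6	angiomyolipoma	TSC2	nonsense	c.1195G>T	p.E399*	25	48	0.34	somatic		2-hit			RNA-Seq
P5	S6	angiomyolipoma	TSC2	frameshift_del	c.2246delG	p.R749fs	21	61	0.26	somatic					
P6	S7	angiomyolipoma	TSC2	genomic_del	NA	NA			0.63	somatic		NA			RNA-Seq; homozygous_del_kb=50; single_copy_loss_kb=150
P7	S8	angiomyolipoma	TSC2	splice	c.2742+1G>A	p.K914_splice	15	38	0.28	somatic		2-hit			no normal
P7	S8	angiomyolipoma	TSC2	inframe_del	c.5227_5244delCGGCTCCGCCACATCAAG	p.RLRHIK1743del	18	215	0.08	somatic					no normal
P8	S9	angiomyolipoma	TSC2	nonsense	c.3581G>A	p.W1194*	56	100	0.36	somatic		2-hit			no normal
P8	S9	angiomyolipoma	TSC2	frameshift_del	c.4565_4566delAT	p.N1522fs	42	123	0.25	somatic					no normal
P9	S10	angiomyolipoma	TSC2	splice	c.3132-1G>C	p.R1044_splice	35	73	0.32	somatic		2-hit			no normal
P9	S10	angiomyolipoma	TSC2	nonsense	c.4905C>A	p.C1635*	15	31	0.33	somatic					no normal
P10	S11	angiomyolipoma	TSC2	nonsense	c.3310C>T	p.Q1104*	8	15	0.35	somatic		2-hit			no normal
P10	S11	angiomyolipoma	TSC2	splice	c.976-15G>A	p.A326_splice	44	144	0.23	somatic					no normal
P11	S12	angiomyolipoma	TSC2	nonsense	c.274G>T	p.E92*	6	10	0.38	somatic		2-hit			no normal
P11	S12	angiomyolipoma	TSC2	nonsense	c.3259G>T	p.E1087*	38	119	0.24	somatic					no normal
P12	S13	angiomyolipoma	TSC2	nonsense	c.4762C>T	p.Q1588*	45	22	0.67	somatic		Yes			no normal
P13	S14	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	84	32	0.72	germline		Yes			TSC
P13	S15	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	370	248	0.60	germline		Yes			TSC
P13	S16	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	69	121	0.36	germline		No			TSC
P13	S17	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	119	42	0.74	germline		Yes			TSC
P13	S18	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	102	34	0.75	germline		Yes			TSC
P13	S19	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	86	76	0.53	germline		Yes			TSC
P13	S20	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	96	53	0.64	germline		Yes			TSC
P13	S21	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	93	53	0.64	germline		Yes			TSC
P13	S22	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	95	97	0.50	germline		Yes			TSC
P13	S23	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	92	84	0.52	germline		Yes			TSC
P13	S24	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	114	48	0.70	germline		Yes			TSC
P13	S25	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	129	54	0.71	germline		Yes			TSC
P13	S26	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	77	104	0.43	germline		2-hit			TSC
P13	S26	angiomyolipoma	TSC2	frameshift_ins	c.888_889insT	p.F297fs	155	345	0.31	somatic					TSC
P13	S27	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	73	134	0.35	germline		2-hit			TSC
P13	S27	angiomyolipoma	TSC2	frameshift_ins	c.2035-2036insG	p.V679fs	26	185	0.12	somatic					TSC
P13	S28	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	72	137	0.34	germline		No			TSC
P13	S29	angiomyolipoma	TSC2	frameshift_del	c.5135delC	p.A1712fs	145	51	0.74	germline		Yes			TSC
P14	S30	angiomyolipoma	TSC1	nonsense	c.2074C>T	p.R692*	121	46	0.72	germline		9q LOH			no normal, TSC
P14	S31	angiomyolipoma	TSC1	nonsense	c.2074C>T	p.R692*	83	60	0.58	germline		9q LOH			no normal, TSC
P15	S32	angiomyolipoma	TSC2	splice	c.2742+1G>A	p.K914_splice	125	123	0.50	somatic		Yes			no normal
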