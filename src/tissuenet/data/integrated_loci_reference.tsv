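gene	de_flag	ts_flag	tissue	fold_change	snp	chrom	pos	distance_bp	side	trait	pvalue
DPPA4	1	0	HYP	-4.82	rs41571491	1	54523895	5517	downstream	HPG	0.00554
TP63	1	1	ADIPOSE	5.06	rs109034747	1	78088393	0	within	FSC	0.00745
INHA	0	1	OVA	-1.26	rs136318374	2	108231291	1460	downstream	ACL	0.00504
IL22RA1	1	0	END	-16.78	rs29019426	2	129348719	2978	upstream	FSC	0.00205
RHEBL1	1	0	PIT	-3.97	rs110770702	5	30912029	7398	upstream	HPG	0.00372
LYSB	0	1	END	-2.02	rs110181782	5	44556197	0	within	ACL	0.00517
ADH6	1	0	END	25.0	rs41612964	6	26799276	0	within	HPG	0.00615
MEPE	1	1	PIT	4.71	rs41650773	6	38286952	0	within	HPG	0.0059
TECRL	0	1	LDM	-1.22	rs109759346	6	81577343	0	within	ACL	0.00746
LOC777593	1	0	END	15.96	rs109621209	7	61683533	0	within	HPG	0.00549
MGC157266	1	0	END	-3.76	rs136828274	8	62927382	8411	upstream	ACL	0.00715
C10H11ORF46	1	1	HYP	-4.16	rs109705635	10	4882326	0	within	ACL	0.00292
NRXN3	1	0	END	-3.92	rs43651752	10	91751584	0	within	HPG	0.00283
TSHR	1	0	END	4.55	ss117964119	10	93528030	0	within	HPG	0.00369
NEBL	1	0	END	5.63	ss61500113	13	22476667	0	within	FSC	0.00157
MOS	0	1	OVA	-2.05	rs110243083	14	24973324	2465	upstream	ACL	0.00017
PENK	1	0	PIT	4.54	rs134428213	14	25218861	0	within	ACL	0.00061
ELF5	1	0	UTE	-17.19	rs133233558	15	65840403	0	within	ACL	0.00879
POU4F2	0	1	END	-2.45	rs41838669	17	11828433	1818	upstream	HPG	0.00707
FAM19A4	1	0	LIV	-4.46	rs136177962	22	32820574	0	within	ACL	0.00712
ITIH1	1	0	OVA	3.48	rs110723544	22	48663639	0	within	HPG	0.00567
CPNE5	1	0	END	-4.95	rs109264326	23	10690330	0	within	ACL	0.00743
MMD2	1	0	UTE	19.89	rs135797510	25	39622260	0	within	ACL	0.00493
DKK1	1	0	UTE	11.65	rs29024937	26	6860529	4762	downstream	FSC	0.00817
SYCE1	0	1	LIV	1.02	rs41629412	26	50517416	0	within	HPG	0.00743
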