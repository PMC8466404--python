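Entry	Gene Names	Gene	Surfaceomic RMS	Transcriptomic RMS	Proteomic Normal	Transcriptomic Normal	Composite Sum	Composite Rank
P55283	CDH4	CDH4	1	17	1	1	20	1
Q58EX2	SDK2 KIAA1514	SDK2	1	6	11	4	22	2
Q96KG7	MEGF10 KIAA1780	MEGF10	15	9	1	1	26	3
O00762	UBE2C UBCH10	UBE2C	23	2	1	1	27	4
P52803	EFNA5 EPLG7 LERK7	EFNA5	1	23	4	10	38	5
P49407	ARRB1 ARR1	ARRB1	1	13	13	18	45	6
P78310	CXADR CAR	CXADR	1	26	6	13	46	7
Q15375	EPHA7 EHK3 HEK11	EPHA7	22	3	17	6	48	8
Q92823	NRCAM KIAA0343	NRCAM	8	1	26	14	49	9
O60245	PCDH7 BHPCDH	PCDH7	13	12	15	11	51	10
P24394	IL4R IL4RA 582J2.1	IL4R	1	21	5	31	58	11
Q15223	NECTIN1 HVEC PRR1 PVRL1	NECTIN1	1	4	35	21	61	12
P23468	PTPRD	PTPRD	18	5	34	7	64	13
O60462	NRP2 VEGF165R2	NRP2	11	30	9	15	65	14
P08581	MET	MET	16	36	8	12	72	15
P13612	ITGA4 CD49D	ITGA4	38	22	10	5	75	16
O14936	CASK LIN2	CASK	9	33	25	9	76	17
P32004	L1CAM CAML1 MIC5	L1CAM	17	11	29	20	77	18
P52292	KPNA2 RCH1 SRP1	KPNA2	14	16	27	22	79	19
Q9P258	RCC2 KIAA1470 TD60	RCC2	26	14	12	27	79	19
Q06787	FMR1	FMR1	10	25	30	17	82	21
P54826	GAS1	GAS1	21	24	16	24	85	22
Q9C0H2	TTYH3 KIAA1691	TTYH3	19	10	33	23	85	22
Q6ZRP7	QSOX2 QSCN6L1 SOXN	QSOX2	36	15	19	16	86	24
P55291	CDH15 CDH14 CDH3	CDH15	37	19	23	8	87	25
Q92974	ARHGEF2 KIAA0651 LFP40	ARHGEF2	12	20	32	26	90	26
Q16658	FSCN1 FAN1 HSN SNL	FSCN1	28	7	28	29	92	27
Q5ZPR3	CD276 B7H3 PSEC0249 UNQ309/PRO352	CD276	29	27	18	19	93	28
P54760	EPHB4 HTK MYK1 TYRO11	EPHB4	31	32	7	28	98	29
Q9BX67	JAM3 UNQ859/PRO1868	JAM3	33	18	21	30	102	30
P09429	HMGB1 HMG1	HMGB1	20	38	14	34	106	31
P49006	MARCKSL1 MLP MRP	MARCKSL1	34	8	38	37	117	32
P50895	BCAM LU MSK19	BCAM	27	31	22	38	118	33
P49327	FASN FAS	FASN	32	34	20	33	119	34
Q9H910	JPT2 C16orf34 HN1L L11	HN1L	30	29	37	25	121	35
Q15691	MAPRE1	MAPRE1	25	28	36	35	124	36
P17612	PRKACA PKACA	PKACA	24	35	31	36	126	37
P34741	SDC2 HSPG1	SDC2	35	37	24	32	128	38
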