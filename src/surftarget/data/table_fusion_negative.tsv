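Entry	Gene Names	Gene	Surfaceomic RMS	Transcriptomic RMS	Proteomic Normal	Transcriptomic Normal	Composite Sum	Composite Rank
P52803	EFNA5 EPLG7 LERK7	EFNA5	1	10	1	3	15	1
Q92823	NRCAM KIAA0343	NRCAM	8	4	12	7	31	2
Q15223	NECTIN1 HVEC PRR1 PVRL1	NECTIN1	1	1	19	13	34	3
O60245	PCDH7 BHPCDH	PCDH7	15	11	5	4	35	4
Q9BY67	CADM1 IGSF4 IGSF4A NECL2 SYNCAM TSLC1	CADM1	1	19	9	6	35	4
P27701	CD82 KAI1 SAR2 ST6 TSPAN27	CD82	1	14	2	20	37	6
O14910	LIN7A MALS1 VELI1	LIN7A	1	17	22	1	41	7
P22455	FGFR4 JTK2 TKF	FGFR4	13	3	20	9	45	8
O14936	CASK LIN2	CASK	7	26	11	2	46	9
Q8NBJ4	GOLM1 C9orf155 GOLPH2 PSEC0242	GOLM1	10	13	3	22	48	10
P54826	GAS1	GAS1	12	16	6	18	52	11
Q06787	FMR1	FMR1	9	18	15	12	54	12
Q9C0H2	TTYH3 KIAA1691	TTYH3	16	7	18	17	58	13
O15020	SPTBN2 KIAA0302 SCA5	SPTBN2	18	2	25	14	59	14
P18065	IGFBP2 BP2 IBP2	IGFBP2	1	5	24	29	59	14
P36639	NUDT1 MTH1	NUDT1	25	12	23	5	65	16
Q16658	FSCN1 FAN1 HSN SNL	FSCN1	24	8	14	21	67	17
Q6ZRP7	QSOX2 QSCN6L1 SOXN	QSOX2	26	24	7	10	67	17
P42574	CASP3 CPP32	CASP3	14	30	13	11	68	19
O96019	ACTL6A BAF53 BAF53A INO80K	ACTL6A	30	23	8	16	77	20
P07093	SERPINE2 PI7 PN1	SERPINE2	27	15	21	15	78	21
P09429	HMGB1 HMG1	HMGB1	20	28	4	26	78	21
P62166	NCS1 FLUP FREQ	NCS1	17	9	28	24	78	21
Q8WXX5	DNAJC9	DNAJC9	21	22	27	8	78	21
P34741	SDC2 HSPG1	SDC2	28	21	10	25	84	25
Q14160	SCRIB CRIB1 KIAA0147 LAP4 SCRB1 VARTUL	SCRIB	19	25	17	23	84	26
P05067	APP A4 AD1	APP	11	29	16	30	86	27
P49006	MARCKSL1 MLP MRP	MARCKSL1	23	6	30	28	87	28
Q9H910	JPT2 C16orf34 HN1L L11	HN1L	22	27	29	19	97	28
Q15691	MAPRE1	MAPRE1	29	20	26	27	102	30
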