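Entry	Gene Names	Gene	Proteomic RMS	Transcriptomic RMS	Proteomic Normal	Transcriptomic Normal	Composite Sum	Composite Rank
P55283	CDH4	CDH4	1	12	1	1	15	1
P52803	EFNA5 EPLG7 LERK7	EFNA5	1	9	2	4	16	2
Q92823	NRCAM KIAA0343	NRCAM	4	1	13	6	24	3
O60245	PCDH7 BHPCDH	PCDH7	9	8	5	5	27	4
Q15375	EPHA7 EHK3 HEK11	EPHA7	18	3	7	2	30	5
Q15223	NECTIN1 HVEC PRR1 PVRL1	NECTIN1	1	2	19	14	36	6
O14936	CASK LIN2	CASK	5	21	12	3	41	7
O60462	NRP2 VEGF165R2	NRP2	7	22	3	9	41	7
P54826	GAS1	GAS1	8	14	6	17	45	9
Q06787	FMR1	FMR1	6	15	16	11	48	10
Q16658	FSCN1 FAN1 HSN SNL	FSCN1	12	5	14	19	50	11
Q6ZRP7	QSOX2 QSCN6L1 SOXN	QSOX2	20	11	10	10	51	12
Q9C0H2	TTYH3 KIAA1691	TTYH3	10	7	18	16	51	12
O15020	SPTBN2 KIAA0302 SCA5	SPTBN2	14	4	20	15	53	14
P32004	L1CAM CAML1 MIC5	L1CAM	15	10	15	13	53	14
Q5ZPR3	CD276 B7H3 PSEC0249 UNQ309/PRO352	CD276	23	13	8	12	56	16
O75051	PLXNA2 KIAA0463 OCT PLXN2 UNQ209/PRO235	PLXNA2	24	16	9	8	57	17
P09429	HMGB1 HMG1	HMGB1	11	24	4	22	61	18
Q8WXX5	DNAJC9	DNAJC9	17	18	22	7	64	19
P49006	MARCKSL1 MLP MRP	MARCKSL1	16	6	24	24	70	20
Q9H910	JPT2 C16orf34 HN1L L11	HN1L	13	19	23	18	73	21
P34741	SDC2 HSPG1	SDC2	22	20	11	21	74	22
Q15691	MAPRE1	MAPRE1	19	17	21	23	80	23
Q14160	SCRIB CRIB1 KIAA0147 LAP4 SCRB1 VARTUL	SCRIB	21	23	17	20	81	24
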