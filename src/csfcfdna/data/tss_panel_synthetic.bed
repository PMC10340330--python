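chr1	100000	102000	MYC	.	+	panel_gene
chr2	100000	102000	MYCN	.	-	panel_gene
chr3	100000	102000	TYR	.	+	panel_gene
chr4	100000	102000	JAK3	.	-	panel_gene
chr5	100000	102000	PDLIM3	.	+	panel_gene
chr6	100000	102000	RELL1	.	-	panel_gene
chr7	100000	102000	EMX2	.	+	panel_gene
chr8	100000	102000	UNC5D	.	-	panel_gene
chr9	100000	102000	FOXN3	.	+	panel_gene
chr10	100000	102000	BAGE3	.	-	panel_gene
chr11	100000	102000	EBT001	.	+	panel_gene
chr12	100000	102000	EBT002	.	-	panel_gene
chr13	100000	102000	EBT003	.	+	panel_gene
chr14	100000	102000	EBT004	.	-	panel_gene
chr15	100000	102000	EBT005	.	+	panel_gene
chr16	100000	102000	EBT006	.	-	panel_gene
chr17	100000	102000	EBT007	.	+	panel_gene
chr18	100000	102000	EBT008	.	-	panel_gene
chr19	100000	102000	EBT009	.	+	panel_gene
chr20	100000	102000	EBT010	.	-	panel_gene
chr21	100000	102000	EBT011	.	+	panel_gene
chr22	100000	102000	EBT012	.	-	panel_gene
chr1	112000	114000	EBT013	.	+	panel_gene
chr2	112000	114000	EBT014	.	-	panel_gene
chr3	112000	114000	EBT015	.	+	panel_gene
chr4	112000	114000	EBT016	.	-	panel_gene
chr5	112000	114000	EBT017	.	+	panel_gene
chr6	112000	114000	EBT018	.	-	panel_gene
chr7	112000	114000	EBT019	.	+	panel_gene
chr8	112000	114000	EBT020	.	-	panel_gene
chr9	112000	114000	EBT021	.	+	panel_gene
chr10	112000	114000	EBT022	.	-	panel_gene
chr11	112000	114000	EBT023	.	+	panel_gene
chr12	112000	114000	EBT024	.	-	panel_gene
chr13	112000	114000	EBT025	.	+	panel_gene
chr14	112000	114000	EBT026	.	-	panel_gene
chr15	112000	114000	EBT027	.	+	panel_gene
chr16	112000	114000	EBT028	.	-	panel_gene
chr17	112000	114000	EBT029	.	+	panel_gene
chr18	112000	114000	EBT030	.	-	panel_gene
chr19	112000	114000	EBT031	.	+	panel_gene
chr20	112000	114000	EBT032	.	-	panel_gene
chr21	112000	114000	EBT033	.	+	panel_gene
chr22	112000	114000	EBT034	.	-	panel_gene
chr1	124000	126000	EBT035	.	+	panel_gene
chr2	124000	126000	EBT036	.	-	panel_gene
chr3	124000	126000	EBT037	.	+	panel_gene
chr4	124000	126000	EBT038	.	-	panel_gene
chr5	124000	126000	EBT039	.	+	panel_gene
chr6	124000	126000	EBT040	.	-	panel_gene
chr7	124000	126000	EBT041	.	+	panel_gene
chr8	124000	126000	EBT042	.	-	panel_gene
chr9	124000	126000	EBT043	.	+	panel_gene
chr10	124000	126000	EBT044	.	-	panel_gene
chr11	124000	126000	EBT045	.	+	panel_gene
chr12	124000	126000	EBT046	.	-	panel_gene
chr13	124000	126000	EBT047	.	+	panel_gene
chr14	124000	126000	EBT048	.	-	panel_gene
chr15	124000	126000	EBT049	.	+	panel_gene
chr16	124000	126000	EBT050	.	-	panel_gene
chr17	124000	126000	EBT051	.	+	panel_gene
chr18	124000	126000	EBT052	.	-	panel_gene
chr19	124000	126000	EBT053	.	+	panel_gene
chr20	124000	126000	EBT054	.	-	panel_gene
chr21	124000	126000	EBT055	.	+	panel_gene
chr22	124000	126000	EBT056	.	-	panel_gene
chr1	136000	138000	EBT057	.	+	panel_gene
chr2	136000	138000	EBT058	.	-	panel_gene
chr3	136000	138000	EBT059	.	+	panel_gene
chr4	136000	138000	EBT060	.	-	panel_gene
chr5	136000	138000	EBT061	.	+	panel_gene
chr6	136000	138000	EBT062	.	-	panel_gene
chr7	136000	138000	EBT063	.	+	panel_gene
chr8	136000	138000	EBT064	.	-	panel_gene
chr9	136000	138000	EBT065	.	+	panel_gene
chr10	136000	138000	EBT066	.	-	panel_gene
chr11	136000	138000	EBT067	.	+	panel_gene
chr12	136000	138000	EBT068	.	-	panel_gene
chr13	136000	138000	EBT069	.	+	panel_gene
chr14	136000	138000	EBT070	.	-	panel_gene
chr15	136000	138000	EBT071	.	+	panel_gene
chr16	136000	138000	EBT072	.	-	panel_gene
chr17	136000	138000	EBT073	.	+	panel_gene
chr18	136000	138000	EBT074	.	-	panel_gene
chr19	136000	138000	EBT075	.	+	panel_gene
chr20	136000	138000	EBT076	.	-	panel_gene
chr21	136000	138000	EBT077	.	+	panel_gene
chr22	136000	138000	EBT078	.	-	panel_gene
chr1	148000	150000	EBT079	.	+	panel_gene
chr2	148000	150000	EBT080	.	-	panel_gene
chr3	148000	150000	EBT081	.	+	panel_gene
chr4	148000	150000	EBT082	.	-	panel_gene
chr5	148000	150000	EBT083	.	+	panel_gene
chr6	148000	150000	EBT084	.	-	panel_gene
chr7	148000	150000	EBT085	.	+	panel_gene
chr8	148000	150000	EBT086	.	-	panel_gene
chr9	148000	150000	EBT087	.	+	panel_gene
chr10	148000	150000	EBT088	.	-	panel_gene
chr11	148000	150000	EBT089	.	+	panel_gene
chr12	148000	150000	EBT090	.	-	panel_gene
chr13	148000	150000	EBT091	.	+	panel_gene
chr14	148000	150000	EBT092	.	-	panel_gene
chr15	148000	150000	EBT093	.	+	panel_gene
chr16	148000	150000	EBT094	.	-	panel_gene
chr17	148000	150000	EBT095	.	+	panel_gene
chr18	148000	150000	EBT096	.	-	panel_gene
chr19	148000	150000	EBT097	.	+	panel_gene
chr20	148000	150000	EBT098	.	-	panel_gene
chr21	148000	150000	EBT099	.	+	panel_gene
chr22	148000	150000	EBT100	.	-	panel_gene
chr1	160000	162000	EBT101	.	+	panel_gene
chr2	160000	162000	EBT102	.	-	panel_gene
chr3	160000	162000	ACTB	.	+	control_ubiquitous
chr4	160000	162000	B2M	.	+	control_ubiquitous
chr5	160000	162000	GAPDH	.	+	control_ubiquitous
chr6	160000	162000	SDHA	.	+	control_ubiquitous
chr7	160000	162000	BAGE4	.	+	control_cns_silent
chr8	160000	162000	ACPT	.	+	control_cns_silent
chr9	160000	162000	SLC32A1	.	+	control_cns_expressed
chr10	160000	162000	CNTNAP2	.	+	control_cns_expressed
chr11	160000	165000	CTNNB1	.	+	coding_region
chr12	160000	165000	PTCH1	.	+	coding_region
chr13	160000	165000	SMARCB1	.	+	coding_region
chr14	160000	165000	SMARCA4	.	+	coding_region
chr15	160000	165000	SMO	.	+	coding_region
chr16	160000	165000	SUFU	.	+	coding_region
chr17	160000	160200	H3F3A_K27M	.	+	hotspot
chr18	160000	160200	HIST1H3B_K27M	.	+	hotspot
chr19	160000	160200	BRAF_V600E	.	+	hotspot
chr20	160000	160200	IDH1_R132C	.	+	hotspot
chr21	160000	160200	IDH2_R172K	.	+	hotspot
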