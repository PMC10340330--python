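patient_id	kind	descriptor	flag	in_tumor	detected_in_csf	csf_note
1	SNV	SMARCB1 c.851C>G p.(Ser284*)	diagnostic	1	1
1	CNA	SMARCB1 loss	diagnostic	1	1
2	CNA	SMARCB1 loss	diagnostic	1	1
3	SNV	SMARCB1 c.601C>T p.(Arg201*)	diagnostic	1	0	non_contributive
4	CNA	2pter-p22.3 gain (subclone)	diagnostic	1	0	non_contributive
4	CNA	chr7 gain	diagnostic	1	0	non_contributive
4	CNA	17q12.2-qter gain	diagnostic	1	0	non_contributive
4	CNA	11pter-p11.12 loss	diagnostic	1	0	non_contributive
4	CNA	17q12.2-qter loss	diagnostic	1	0	non_contributive
5	SNV	CTNNB1 c.100G>A p.(Gly34Arg)	diagnostic	1	1
5	CNA	chr6 loss	diagnostic	1	0
5	CNA	chr2pter-p13.2 gain	diagnostic	1	1
6	CNA	17q gain	diagnostic	1	0	non_contributive
6	CNA	17p loss	diagnostic	1	0	non_contributive
7	CNA	chr10 loss	diagnostic	1	0	non_contributive
7	CNA	chr2 loss	diagnostic	1	0	non_contributive
7	CNA	chr11 loss	diagnostic	1	0	non_contributive
7	CNA	chr13 loss	diagnostic	1	0	non_contributive
7	CNA	chr16 loss	diagnostic	1	0	non_contributive
7	CNA	chr20 loss	diagnostic	1	0	non_contributive
8	CNA	1q gain	diagnostic	1	1
8	CNA	chr2 gain	diagnostic	1	1
8	CNA	chr10 gain	diagnostic	1	1
8	CNA	chr20 gain	diagnostic	1	1
8	CNA	1p loss	diagnostic	1	0
8	CNA	chr3 loss	diagnostic	1	1
8	CNA	chr9 loss	diagnostic	1	1
8	CNA	chr12 loss	diagnostic	1	1
8	CNA	chr14 loss	diagnostic	1	1
8	CNA	chr15 loss	diagnostic	1	1
8	CNA	chr19 loss	diagnostic	1	1
8	CNA	chrX loss	diagnostic	1	0
9	CNA	17p loss	diagnostic	1	0	non_contributive
9	CNA	17q gain	diagnostic	1	0	non_contributive
10	CNA	2p24.3-2 amplicon (MYCN)	diagnostic	1	1
10	CNA	5q31.2-ter loss	diagnostic	1	1
10	CNA	8q12.3-ter loss	diagnostic	1	1
10	CNA	10q loss	diagnostic	1	0
10	CNA	16q loss	diagnostic	1	0
10	CNA	17pter-p11.2 loss	diagnostic	1	1
10	CNA	10p gain	diagnostic	1	0
10	CNA	17p11.2-qter gain	diagnostic	1	1
11	SNV	PTCH1 c.1359_1360insG p.(Cys454ValfsTer43)	diagnostic	1	0	non_contributive
11	CNA	9q loss	diagnostic	1	0	non_contributive
11	CNA	3q gain	diagnostic	1	0	non_contributive
12	SNV	APC c.3183_3187del p.(Gln1062*) germline	diagnostic	1	1
12	SNV	APC c.3758del p.(Ser1253LeufsTer12)	diagnostic	1	1
12	CNA	chr6 monosomy	diagnostic	1	1
13	CNA	17p loss	diagnostic	1	1
13	CNA	17pq gain	diagnostic	1	1
15	SNV	CCND3 c.774_775delCTinsTG p.(Ser259Ala)	diagnostic	1	0	genes_not_in_panel
15	SNV	COL3A1 c.946G>A p.(Ala316Thr)	diagnostic	1	0	genes_not_in_panel
15	SNV	FANCD2 c.1588C>T p.(Arg530*)	diagnostic	1	0	genes_not_in_panel
15	SNV	NCKIPSD c.1650_1651delGCinsTT p.(Pro551Ser)	diagnostic	1	0	genes_not_in_panel
15	SNV	PTPRC c.3452A>G p.(Lys1151Arg)	diagnostic	1	0	genes_not_in_panel
16	CNA	1q(210.34Mb-tel) gain	diagnostic	1	0	non_contributive
16	CNA	3p(tel-5.17Mb) gain	diagnostic	1	0	non_contributive
17	CNA	17p(tel-18.91Mb) loss (TP53)	diagnostic	1	1
17	CNA	17pq(19.14Mb-tel) gain	diagnostic	1	1
18	CNA	11p loss	diagnostic	1	0	non_contributive
18	CNA	17p(tel-22.22Mb) loss	diagnostic	1	0	non_contributive
18	CNA	4q(142.07Mb-tel) gain	diagnostic	1	0	non_contributive
18	CNA	13q(90.81-96.80Mb) gain	diagnostic	1	0	non_contributive
18	CNA	15q(54.53Mb-tel) gain	diagnostic	1	0	non_contributive
18	CNA	17pq(25.28Mb-tel) gain	diagnostic	1	0	non_contributive
18	CNA	7q(92.20-96.80Mb) amplicon (CDK6)	diagnostic	1	0	non_contributive
19	CNA	2q(213.21Mb-tel) loss	diagnostic	1	0	no_cn_analysis
19	CNA	8p(tel-10.18Mb) loss	diagnostic	1	0	no_cn_analysis
19	CNA	16q(57.83Mb-tel) loss	diagnostic	1	0	no_cn_analysis
19	CNA	17p(tel-18.15Mb) loss	diagnostic	1	0	no_cn_analysis
19	CNA	X(78.64-tel) loss	diagnostic	1	0	no_cn_analysis
19	CNA	X(16.68-17.87Mb) loss	diagnostic	1	0	no_cn_analysis
19	CNA	4q(170.70Mb-tel) loss (subclonal)	diagnostic	1	0	no_cn_analysis
19	CNA	5q(170.87Mb-tel) loss (subclonal)	diagnostic	1	0	no_cn_analysis
19	CNA	8q(55.00-70.23Mb) loss (subclonal)	diagnostic	1	0	no_cn_analysis
19	CNA	9p(tel-11.78Mb) loss (subclonal)	diagnostic	1	0	no_cn_analysis
19	CNA	10q(107.71Mb-tel) loss (subclonal)	diagnostic	1	0	no_cn_analysis
19	CNA	12q(40.77-57.69Mb) loss (subclonal)	diagnostic	1	0	no_cn_analysis
20	SNV	CTNNB1 c.98C>G p.(Ser33Cys)	diagnostic	1	1
20	SNV	PIK3CA c.311C>G p.(Pro104Arg)	diagnostic	1	0
20	CNA	chr6 monosomy	diagnostic	1	0	no_cn_analysis
21	CNA	17p(tel-18.91Mb) loss	diagnostic	1	0	no_cn_analysis
21	CNA	17pq(19.14Mb-tel) gain	diagnostic	1	0	no_cn_analysis
22	CNA	16q(66.57Mb-tel) loss	diagnostic	1	0	no_cn_analysis
22	CNA	8q(52.57Mb-tel) loss (subclonal)	diagnostic	1	0	no_cn_analysis
22	CNA	11q(75.97Mb-tel) loss (subclonal)	diagnostic	1	0	no_cn_analysis
22	CNA	13q(25.30-31.39Mb) loss (subclonal)	diagnostic	1	0	no_cn_analysis
22	CNA	13q(50.05-81.10Mb) loss (subclonal)	diagnostic	1	0	no_cn_analysis
22	CNA	7p(tel-4.88Mb) gain	diagnostic	1	0	no_cn_analysis
22	CNA	13q(20.28-25.27Mb) gain	diagnostic	1	0	no_cn_analysis
22	CNA	13q(31.45-49.99Mb) gain	diagnostic	1	0	no_cn_analysis
22	CNA	13q(81.14Mb-tel) gain	diagnostic	1	0	no_cn_analysis
22	CNA	17q(46.78Mb-tel) gain	diagnostic	1	0	no_cn_analysis
23	CNA	19q13.41 amplification (C19MC)	diagnostic	1	1
24	SNV	PTPRK p.(Thr395AspfsTer6)	diagnostic	1	0	non_contributive
24	CNA	1q gain	suggestive	1	1
24	CNA	chr7 gain	diagnostic	1	0
24	CNA	8q gain	diagnostic	1	0
25	SNV	KDR p.(His1144Asp)	diagnostic	1	0	non_contributive
25	SNV	TP53 p.(Arg175His)	diagnostic	1	0	non_contributive
25	SNV	KRAS p.(Gly12Asp)	diagnostic	1	0	non_contributive
25	CNA	chr2 gain	diagnostic	1	1
25	CNA	chr7 gain	diagnostic	1	1
25	CNA	chr12 gain	diagnostic	1	1
25	CNA	chr19 gain	diagnostic	1	1
25	CNA	chr20(30.5-30.8Mb) amplification	diagnostic	1	1
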