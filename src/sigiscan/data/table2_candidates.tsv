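gene_name	locus_tags	organism	aligned_sequence	utr_5p	validated_by	tss_offset	atcc27405_status	description
xyn10Z	Clo1313_2635,Cthe_1963	Ct	ACCGACACAAAAATGTGAGCGTTCACGAAACAATAAATAT	96	sigI6	39	intact	cellulosomal xylanase CE1-CBM6-Doc-GH10
xyn11B	Clo1313_0522,Cthe_2972	Ct	AGCGACTTAAAAAATTATATTTTTGCGAATAGATAATATG	164	sigI6	39	intact	cellulosomal xylanase GH11-CBM6-Doc; first gene of xyn11B-xyn11A operon in DSM 1313
ce8	Clo1313_0500,Cthe_2949	Ct	CCCCGCTCAAATGTTGCATAAACCTCGAATCTTAAAATAA	32	none		intact	carbohydrate esterase family 8
ce12	Clo1313_0693,Cthe_3141	Ct	TACCCTTAAAAAAACTTGCT-TCTACGTATTTTAATATTA	51	sigI3		intact	cellulosomal pectinase RGAE-Doc-CBM35-RGAE
cel5E	Clo1313_1425,Cthe_0797	Ct	GCTGTCCAAAAGAAAA-TGATTTTTCGAATTAATATAATA	156	none		intact	endoglucanase GH5
cel8A	Clo1313_1960,Cthe_0269	Ct	ACCCTATCAAATAACCCATTCAATTCGCATTTATTTTAAG	254	none		intact	endoglucanase GH8
cel9J	Clo1313_1604,Cthe_0624	Ct	GCCCCCTTAAAAAATTTTA-AAATTCGAAATTAATTTTTG	477	none		intact	endoglucanase GH9
cel9P	Clo1313_1955,Cthe_0274	Ct	AACGTCTATAATTTTTT-ATGATAACGATAAAATTAAATT	19	none		intact	endoglucanase GH9
cel9Q	Clo1313_1603,Cthe_0625	Ct	ACCCACTTAAAAATGTGTATGTGCACGGATTTCTATTTGG	375	none		intact	endoglucanase GH9
cel9U	Clo1313_3023,Cthe_2360	Ct	AGCCCCTCAAAAATTTTTTCCCTTTCGAATATATATAGAT	394	none		intact	endoglucanase GH9; ATCC 27405 carries an extra T at the 5' end (AGCTCCCTCAAA)
cel9V	Clo1313_0349,Cthe_2760	Ct	ATACCCATAAAATTTTTATGTTCTACGAATATATAATATA	124	sigI6		intact	cellulosomal endoglucanase GH9-2(CBM3)-Doc
cel48S	Clo1313_2747,Cthe_2089	Ct	GCCCCCTCAAAAAGTATATTTTTTTCGAAGATATATATAT	498	none		intact	exoglucanase GH48, most abundant cellulosomal enzyme
cenC	Clo1313_0420,Cthe_2879	Ct	CCCAATCGAAAAAAGAACATGTCATCGAATCTATATATCA	102	none		intact	endoglucanase
cipA	Clo1313_0627,Cthe_3077	Ct	TGCCCCTCAAATTCCGTTTATATATCGAATATATATTACA	846	sigI6+sigI3		intact	cellulosomal scaffoldin 2(Coh)-CBM3-6(Coh)-X-Doc
cseP	Clo1313_2188,Cthe_0044	Ct	TAAGCCACAAAATTATTT-TTTCTACGAATATATATTGAA	132	sigI6		intact	cellulosomal component CotH-Doc
pelB2	Clo1313_0501,Cthe_2950	Ct	TCCCAATGAAATACGACCCTTGATACGTATTATTAATATA	67	none		intact	pectate lyase
pilZ	Clo1313_1490,Cthe_0733	Ct	GCCCCCTCAAAATA-TGAGAACATTCGAAATATTATAATA	321	none		intact	PilZ-domain protein
pl11	Clo1313_1983,Cthe_0246	Ct	CTACCCCTAAAAAAA-TTAGAATTTCGTATTTATAAAAAG	39	sigI3		intact	cellulosomal pectinase Doc-CBM35-RGL11
rsgI5	Clo1313_0985,Cthe_1273	Ct	ATGGACCAAAAAGTACTTTCAAACACGAAATTATTAAATA	43	sigI6		intact	anti-sigma-I5 factor RsgI_N-UNK-CBM42
rsgI9	Clo1313_1969,Cthe_0260	Ct	CTCTAAAAATATCGGGATTTTTTTCCGAAATAACTAATAG	31	none		intact	anti-sigma-I9 factor
sdbA	Clo1313_0950,Cthe_1307	Ct	CAACGCTCAATACGAACTCTTTCTCCGAATTTATTCTATT	157	none		intact	cell-surface anchoring protein SdbA
xgh74A	Clo1313_0851,Cthe_1398	Ct	GGTACATCAAAGGAAAGTACAGGTCCGAATTTATATAGCG	147	none		intact	xyloglucanase GH74
xyn10D	Clo1313_0177,Cthe_2590	Ct	TGCGACCAAAAGGCGTCAAATTTCACGAAATACATATAAA	33	sigI6		intact	cellulosomal xylanase CBM22-GH10-Doc
xyn10Y	Clo1313_1305,Cthe_0912	Ct	CCCAACGTAAAAATTCAATACCTTTCGAATAAATAACATA	277	sigI6		intact	cellulosomal xylanase CBM22-GH10-CBM22-Doc-CE1
Clo1313_0563	Clo1313_0563,Cthe_3012	Ct	CCGTACATAAAAAGAAGTTTTGATTCGAATAATTAACACA	67	none		intact	GH30-CBM6-Doc
Clo1313_0987	Clo1313_0987,Cthe_1271	Ct	CCCAACCCAAACTTGCCATATGTTTCGTACAAATAAATTG	67	none		intact	GH43-2xCBM6-Doc
Clo1313_1436	Clo1313_1436,Cthe_0785	Ct	ATCCCCTTTAAGAATTGACATAAAACGCATTAACTATTAT	106	none		intact	hypothetical protein
Clo1313_1494	Clo1313_1494,Cthe_0729	Ct	ACGGAAATAAAAACAACTCCAATTACGAATAAATATACCA	35	none		intact	HP-Doc
Clo1313_2216	Clo1313_2216,Cthe_0015	Ct	CCCACTCCAAAAAACATTTAATTCTCGTATTATTATAACA	46	none		intact	GH43-CBM42-Doc
Clo1313_2793	Clo1313_2793,Cthe_2137	Ct	CTCAACTTAAAAAATACATTCTTCTCGTATATGTAAGTTA	160	none		interrupted	GH39-2xCBM35-Doc; Cthe_2137 interrupted by an IS element in ATCC 27405
Clo1313_2794	Clo1313_2794,Cthe_2138	Ct	TACGTCACAAACCAAAAACCCAGAACGAACCAATTAATAA	121	none		intact	GH43-CBM42-Doc
Clo1313_2861	Clo1313_2861,Cthe_2197	Ct	CCCAACTAAAAAAAATAGGTACTTCCGTAAAAGTAAAACA	163	none		interrupted	GH2-CBM6-Doc; Cthe_2197 interrupted by an IS element in ATCC 27405
Clo1313_2866	Clo1313_2866	Ct	TAACCCTAAAAATTTAATGCCGATTCGAATAAAAAAGCCT	149	none		absent	ABC transporter ATP-binding protein; no ortholog in ATCC 27405
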