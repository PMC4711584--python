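gene_name	locus_tags	organism	aligned_sequence	utr_5p	validated_by	tss_offset	atcc27405_status	description
sigI1	Clo1313_2174,Cthe_0058	Ct	TAATATACACAAAAAAA-GCAGATGTATACGAAGTAATCTACTG	16	sigI6	43	intact	sigI1-rsgI1; RsgI C-term CBM3
sigI1	JCM21531_2023	Cs	TAATATACATAAAAAAA-GCAGGCTTGAACGAAGTAATCTACTG	17	none		intact	sigI1-rsgI1; RsgI C-term CBM3
sigI2	Clo1313_1961,Cthe_0268	Ct	TGGTATCCCCCGAAAAAATGTTCCCTTTACGAAATAACTAGTAA	147	none		intact	sigI2-rsgI2; RsgI C-term CBM3
sigI2	JCM21531_2790	Cs	TGATATCCCCCTAAAATTTGTTCCTCTTACGAAATAACTTATTA	159	none		intact	sigI2-rsgI2; RsgI C-term CBM3
sigI3	Clo1313_1911,Cthe_0315	Ct	TATGAACCCCTCAAAAAAATCATTTGGTGCGTACAAGTATTGAA	13	sigI3		intact	sigI3-rsgI3; RsgI C-term 2xPA14
sigI3	JCM21531_2365	Cs	TGTAAACCCCTCAAAAAA-TAACTTTGTGCGTACAAGTATTAAA	15	none		intact	sigI3-rsgI3; RsgI C-term 2xPA14
sigI4	Clo1313_1818,Cthe_0403	Ct	AACGTCCAGCTGAAAATTTTCTGCCACGCCGCATTAATTTTTTT	13	none		intact	sigI4-rsgI4; RsgI C-term CBM3
sigI4	JCM21531_1812	Cs	AACGTCCAACTAAAAGTTTGTTGCCACATCGCATTAATCTATTT	13	none		intact	sigI4-rsgI4; RsgI C-term CBM3
sigI6	Clo1313_2778,Cthe_2120	Ct	ACAATGCGACATAAAACCATTCCGGTATACGAATCGATATAAGA	20	sigI6	43	intact	sigI6-rsgI6; RsgI C-term GH10
sigI6	JCM21531_4109	Cs	ATGATGCGACATAAAGCTATTCCAGTCTACGAATTCATATAGGA	22	none		intact	sigI6-rsgI6; RsgI C-term GH10
sigI7	Clo1313_0104,Cthe_2521	Ct	ATTCGACTGATGTTATT-TAAATTTGTGTCGAACTTTGCTGATG	52	none		intact	sigI7-rsgI7; RsgI C-term unknown
sigI7	JCM21531_3721	Cs	ATTCGACTAGTGGTTTG-TAGATTTATGTCGAACTTTGCTGACA	61	none		intact	sigI7-rsgI7; RsgI C-term unknown
sigI8	Clo1313_0525,Cthe_2975	Ct	ACTTTCCGAATCAAAATGAAATCCATATACGAATTTTCTATAGT	16	none		intact	sigI8-rsgI8; RsgI C-term unknown
sigI8	JCM21531_4043	Cs	TTTTACCGAATTAAAATAGAAGTCATATACGAATCCTCTATAGC	18	none		intact	sigI8-rsgI8; RsgI C-term unknown
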