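set_name	row_count	source_file	source_table	consensus_note
ct_sigI_table1	7	table1_sigI_promoters.tsv	Table 1	C-----AAA 13-14(N) CGWA
cs_sigI_table1	7	table1_sigI_promoters.tsv	Table 1	C-----AAA 13-14(N) CGWA
sigI_table1	14	table1_sigI_promoters.tsv	Table 1	C-----AAA 13-14(N) CGWA
ct_candidates_table2	33	table2_candidates.tsv	Table 2	AAA 13-14(N) CGWA----TW
sigI6_validated	10	table1_sigI_promoters.tsv,table2_candidates.tsv	Tables 1-3	CNNAAA 13-14(N) CGAA
sigI3_validated	4	table1_sigI_promoters.tsv,table2_candidates.tsv	Tables 1-2,4	CCCYYAAA 13-14(N) CGWA
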