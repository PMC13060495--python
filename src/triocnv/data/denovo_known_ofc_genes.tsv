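# De novo CNVs in syndromic orofacial-cleft probands overlapping genes with
# established craniofacial roles, as published in the source cohort report.
# Coordinates are transcribed verbatim (half-open; size = end - start).
Patient_ID	Chr	Start	End	CNV_Size_bp	CNV_Type	ACMG_Class	Top_Gene	Genes	Exomiser_Score
GH20140599.1	12	153887435	159145021	5257586	DEL	5	SHH	SHH	0.7396
GH20207072.1	12	14695982	14843363	147381	DEL	5	WBP11	WBP11	0.7369
GH20228117.1	5	179344941	179345578	637	DEL	5	ADAMTS2	ADAMTS2	0.5145
GH20130815.1	12	63779711	63809342	29631	DUP	3	RXYLT1	RXYLT1	0.6560
GH20135043.1	15	33863889	33864439	550	DUP	3	RYR3	RYR3	0.5056
GH20160169.1	5	42628789	42629353	564	DUP	3	GHR	GHR	0.5698
GH20172509.1	22	20709046	20713039	3993	DUP	3	PI4KA	PI4KA	0.6915
GH20218033.1	11	120802444	121629813	827369	DUP	3	SC5D	SC5D	0.7610
GH20218033.1	17	7512973	7514429	1456	DUP	3	POLR2A	POLR2A	0.6089
GH20218075.1	22	20711100	20713039	1939	DUP	3	PI4KA	PI4KA	0.7570
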