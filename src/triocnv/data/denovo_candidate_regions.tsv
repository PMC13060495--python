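# Other de novo CNVs in the same syndromic orofacial-cleft cohort with
# potential craniofacial relevance, transcribed verbatim from the published
# report, including its printed thousands separators. Exomiser scores were
# published only for ETS1 and FLI1; the remaining genes scored below the 0.5
# threshold and their exact values were not printed, so they are NA here.
Patient_ID	Chr	Start	End	CNV_Size_bp	CNV_Type	ACMG_Class	Top_Gene	Genes	Exomiser_Score
GH20130774.1	7	6,780,559	6,815,095	34,536	DUP	3	RSPH10B2	RSPH10B2;CCZ1B	NA
GH20130799.1	7	6,796,319	6,824,594	28,275	DUP	3	RSPH10B2	RSPH10B2;CCZ1B	NA
GH20134969.1	7	6,780,559	6,799,529	18,970	DEL	3	RSPH10B2	RSPH10B2;CCZ1B	NA
GH20207012.1	7	6,780,560	6,824,594	44,034	DEL	3	RSPH10B2	RSPH10B2;CCZ1B	NA
GH20207031.1	7	6,780,559	6,799,529	18,970	DEL	3	RSPH10B2	RSPH10B2;CCZ1B	NA
GH20140607.1	7	6,780,559	6,797,016	16,457	DEL	3	RSPH10B2	RSPH10B2	NA
GH20140628.1	7	6,780,559	6,797,016	16,457	DUP	3	RSPH10B2	RSPH10B2	NA
GH20140628.1	16	70,943,562	70,979,291	35,729	DUP	3	HYDIN	HYDIN	NA
GH20218033.1	11	128,462,112	128,573,380	111,268	DUP	3	ETS1	ETS1;MIR6090;ETS1-AS1;LOC124902790;LOC105369565	0.5697
GH20218033.1	11	128,781,709	129,192,448	410,739	DUP	3	FLI1	FLI1;KCNJ1;LOC107984409;KCNJ5;KCNJ5-AS1;TP53AIP1;ARHGAP32	0.5119
GH20134915.1	22	18,912,925	18,917,238	4,313	DEL	4	PRODH	PRODH	NA
GH20207012.1	22	18,528,750	18,917,238	388,488	DEL	4	PRODH	PRODH;TMEM191B;PI4KAP1;LOC124905077;LOC124905174;LOC124900482;RIMBP3;FAM246B;FAM230E;FAM247C;GGT3P;POM121L15P;LOC102724728;FAM230F;DGCR6	NA
GH20218061.1	22	18,528,750	18,917,238	388,488	DUP	3	PRODH	PRODH;TMEM191B;PI4KAP1;LOC124905077;LOC124905174;LOC124900482;RIMBP3;FAM246B;FAM230E;FAM247C;GGT3P;POM121L15P;LOC102724728;FAM230F;DGCR6	NA
GH20238200.1	22	18,528,750	18,917,238	388,488	DEL	5	PRODH	PRODH;TMEM191B;PI4KAP1;LOC124905077;LOC124905174;LOC124900482;RIMBP3;FAM246B;FAM230E;FAM247C;GGT3P;POM121L15P;LOC102724728;FAM230F;DGCR6	NA
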