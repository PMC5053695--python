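gene_pair	chromosome	donor_transcript	donor_exon	acceptor_transcript	acceptor_exon	intergenic_bp	n_patients	validation_status	frame_maintained	variant	source	notes
ARF3-FKBP11	12	NM_001659	4	NM_001143781	2	9249		validated_different_isoform	no		sanger	
ARF3-FKBP11	12	NM_001659	4	NM_001143781	3	9249		validated_different_isoform	no		sanger	
CD59-C11orf91	11	NM_203331	4	NM_001166692	2	NA		validated_different_isoform	no	intragenic_inclusion	sanger	
ELAVL1-TIMM44	19	NM_001419	4	NM_006351	2	14658		validated_different_isoform	no		sanger	
HARS2-ZMAT2	5	NM_012208	13	NM_144723	2	NA		validated_different_isoform	no	incomplete_exon	sanger	
HSD17B11-HSD17B13	4	NM_016245	6	NM_178135	2	13704		validated_different_isoform	no		sanger	
NAA60-CLUAP1	16	NM_001083601	2	NM_015041	2	13961		validated_different_isoform	no		sanger	
NKX2-1-SFTA3	14	NM_001079668	1	NM_001101341	2	2568		validated_different_isoform	no	incomplete_exon	sanger	
PACSIN2-ARFGAP3	22	NM_001184970	10	NM_001142293	2	NA		validated_different_isoform	no		sanger	
PLEKHO2-ANKDD1A	15	NM_001195059	5	NM_182703	4	43895		validated_different_isoform	yes		sanger	
PLEKHO2-ANKDD1A	15	NM_001195059	5	NM_182703	5	43895		validated_different_isoform	yes		sanger	
PPRC1-NOLC1	10	NM_015062	13	NM_004741	2	1851		validated_different_isoform	no		sanger	
SNTB2-VPS4A	16	NM_006750	6	NM_013245	2	2304		validated_different_isoform	yes		sanger	
SPECC1L-ADORA2A	22	NM_015330	14	NM_000675	3	139		validated_different_isoform	yes		sanger	
TSTD1-F11R	1	NM_001113205	1	NM_016946	2	16283		validated_different_isoform	yes		sanger	
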