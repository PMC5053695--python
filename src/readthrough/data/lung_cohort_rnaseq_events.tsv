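gene_pair	chromosome	donor_transcript	donor_exon	acceptor_transcript	acceptor_exon	intergenic_bp	n_patients	validation_status	frame_maintained	variant	source	notes
AGRP-ATP6V0D1	16	NM_001138	3	NM_004691	2	1334	1	validated_as_predicted	no		rnaseq	
ARF3-FKBP11	12	NM_001659	4	NM_001143781	4	9249	1	not_validated	unassessed		rnaseq	different_isoform_found
ARPC4-TTLL3	3	NM_001024959	5	NM_001025930	2	360	10	validated_as_predicted	no		rnaseq	
CD59-C11orf91	11	NM_203331	4	NM_001166692	2	NA	2	not_validated	unassessed		rnaseq	different_isoform_found
CHIA-PIFO	1	NM_021797	8	NM_181643	2	25722	1	validated_as_predicted	yes		rnaseq	
CTSC-RAB38	11	NM_001814	5	NM_022337	2	118125	2	validated_as_predicted	yes		rnaseq	
CTSC-RAB38	11	NM_001814	4	NM_022337	2	118125	1	not_validated	unassessed		rnaseq	sequencing_excluded
CTSD-IFITM10	11	NM_001909	8	NM_001170820	2	2161	3	validated_as_predicted	yes		rnaseq	
CTSD-IFITM10	11	NM_001909	7	NM_001170820	2	2161	2	not_validated	unassessed		rnaseq	sequencing_excluded
ELAVL1-TIMM44	19	NM_001419	4	NM_006351	3	14658	2	not_validated	unassessed		rnaseq	different_isoform_found
FAM162B-ZUFSP	6	NM_001085480	3	NM_145062	2	83406	1	validated_as_predicted	no		rnaseq	
FARSA-SYCE2	19	NM_004461	12	NM_001105578	3	3203	1	validated_as_predicted	yes		rnaseq	
HARS2-ZMAT2	5	NM_012208	13	NM_144723	2	NA	1	not_validated	unassessed		rnaseq	different_isoform_found
HSD17B11-HSD17B13	4	NM_016245	5	NM_178135	2	13704	1	not_validated	unassessed		rnaseq	different_isoform_found
IFNAR2-IL10RB	21	NM_207584	7	NM_000628	2	683	1	validated_as_predicted	yes		rnaseq	
IFNAR2-IL10RB	21	NM_207584	7	NM_000628	3	683	1	validated_as_predicted	no		rnaseq	
INMT-FAM188B	7	NM_001199219	2	NM_032222	2	13815	4	validated_as_predicted	no		rnaseq	
INMT-FAM188B	7	NM_001199219	2	NM_032222	3	13815	7	not_validated	unassessed		rnaseq	sequencing_excluded
INMT-FAM188B	7	NM_001199219	3	NM_032222	3	13815	1	not_validated	unassessed		rnaseq	no_amplification
KIAA1841-C2orf74	2	NM_032506	21	NM_001143960	2	NA	1	validated_as_predicted	no		rnaseq	
LMAN2-MXD3	5	NM_006816	7	NM_001142935	4	18805	1	validated_as_predicted	yes		rnaseq	
MBD1-CFAP53	18	NM_001204139	14	NM_145020	2	360	1	validated_as_predicted	no		rnaseq	
MED22-SURF6	9	NM_133640	4	NM_006753	2	1925	1	validated_as_predicted	no		rnaseq	
MRPS17-GBAS	7	NM_015969	1	NM_001202469	3	NA	1	not_validated	unassessed		rnaseq	no_amplification
NAA60-CLUAP1	16	NM_001083601	1	NM_015041	2	13961	1	not_validated	unassessed		rnaseq	different_isoform_found
NDUFB8-SEC31B	10	NM_005004	4	NM_015490	2	NA	1	validated_as_predicted	no		rnaseq	
NFATC3-PLA2G15	16	NM_173165	9	NM_012320	2	16045	2	validated_as_predicted	yes		rnaseq	
NKX2-1-SFTA3	14	NM_001079668	2	NM_001101341	4	2568	5	validated_as_predicted	no		rnaseq	
NKX2-1-SFTA3	14	NM_001079668	2	NM_001101341	2	2568	2	validated_as_predicted	no		rnaseq	
NKX2-1-SFTA3	14	NM_001079668	1	NM_001101341	2	2568	1	validated_as_predicted	no		rnaseq	
NKX2-1-SFTA3	14	NM_001079668	1	NM_001101341	4	2568	3	not_validated	unassessed		rnaseq	different_isoform_found
NKX2-1-SFTA3	14	NM_001079668	1	NM_001101341	3	2568	5	not_validated	unassessed		rnaseq	sequencing_excluded
PACSIN2-ARFGAP3	22	NM_001184970	10	NM_001142293	3	NA	1	validated_as_predicted	no		rnaseq	
PACSIN2-ARFGAP3	22	NM_001184970	10	NM_001142293	4	NA	1	not_validated	unassessed		rnaseq	different_isoform_found
PIR-FIGF	X	NM_001018109	9	NM_004469	2	423	1	validated_as_predicted	no		rnaseq	
PLEKHO2-ANKDD1A	15	NM_001195059	2	NM_182703	5	43895	1	validated_as_predicted	yes		rnaseq	
PLEKHO2-ANKDD1A	15	NM_001195059	4	NM_182703	5	43895	1	not_validated	unassessed		rnaseq	different_isoform_found
PPRC1-NOLC1	10	NM_015062	13	NM_004741	4	1851	1	not_validated	unassessed		rnaseq	different_isoform_found
SCNN1A-TNFRSF1A	12	NM_001159575	12	NM_001065	2	4729	2	validated_as_predicted	yes		rnaseq	
SCNN1A-TNFRSF1A	12	NM_001159575	12	NM_001065	3	4729	2	not_validated	unassessed		rnaseq	sequencing_excluded
SCNN1A-TNFRSF1A	12	NM_001159575	13	NM_001065	2	4729	1	not_validated	unassessed		rnaseq	no_amplification
SCNN1A-TNFRSF1A	12	NM_001159575	10	NM_001065	2	4729	1	not_validated	unassessed		rnaseq	sequencing_excluded
SCNN1A-TNFRSF1A	12	NM_001159575	9	NM_001065	2	4729	1	not_validated	unassessed		rnaseq	sequencing_excluded
SFTPC-BMP1	8	NM_003018	3	NM_001199	2	257	2	validated_as_predicted	no		rnaseq	
SHANK3-ACR	22	NM_033517	22	NM_001097	2	4898	1	validated_as_predicted	yes		rnaseq	
SIRPB1-SIRPD	20	NM_001083910	2	NM_178460	2	4678	1	validated_as_predicted	yes		rnaseq	
SNTB2-VPS4A	16	NM_006750	6	NM_013245	3	2304	1	not_validated	unassessed		rnaseq	different_isoform_found
SPECC1L-ADORA2A	22	NM_015330	13	NM_000675	3	139	1	not_validated	unassessed		rnaseq	different_isoform_found
TSTD1-F11R	1	NM_001113205	1	NM_016946	3	16283	2	not_validated	unassessed		rnaseq	different_isoform_found
VAMP8-VAMP5	2	NM_003761	2	NM_006634	2	2377	5	validated_as_predicted	yes		rnaseq	
ZDHHC1-TPPP3	16	NM_013304	10	NM_016140	3	884	1	validated_as_predicted	no		rnaseq	
ZNF343-SNRPB	20	NM_024325	6	NM_198216	2	10964	1	not_validated	unassessed		rnaseq	no_amplification
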