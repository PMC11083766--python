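scf1	braker	gene	150	250	.	+	.	gene_id "g1";
scf1	braker	exon	150	240	.	+	.	gene_id "g1";
scf1	braker	gene	1000	1400	.	+	.	gene_id "g2";
scf1	braker	gene	1500	2000	.	+	.	gene_id "g3";
scf1	braker	gene	3000	4000	.	+	.	gene_id "g4";
scf1	braker	gene	5000	5500	.	+	.	gene_id "g5";
scf1	braker	gene	7400	7700	.	+	.	gene_id "g6";
scf1	braker	gene	8200	8600	.	+	.	gene_id "g7";
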