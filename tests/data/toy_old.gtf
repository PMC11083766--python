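scf1	prev	gene	100	200	.	+	.	gene_id "aug3.g1"; gene_name "replace_me";
scf1	prev	exon	100	180	.	+	.	gene_id "aug3.g1";
scf1	prev	gene	1000	2000	.	+	.	gene_id "aug3.g2";
scf1	prev	gene	3000	3400	.	+	.	gene_id "aug3.g3";
scf1	prev	gene	3500	4000	.	+	.	gene_id "aug3.g4";
scf1	prev	gene	6000	6500	.	+	.	gene_id "aug3.g5";
scf1	prev	gene	7000	7600	.	+	.	gene_id "aug3.g6";
scf1	prev	gene	7650	8300	.	+	.	gene_id "aug3.g7";
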