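##gff-version 3
##sequence-region fig3d_maintainer 1 3770
fig3d_maintainer	mitocms	region	1	3770	.	+	.	ID=fig3d_maintainer:region;Is_circular=true
fig3d_maintainer	mitocms	gene	425	982	.	-	.	ID=gene0:rpl5;Name=rpl5;gene_category=protein_coding;start_codon=ATG;copies=1
fig3d_maintainer	mitocms	CDS	425	982	.	-	0	ID=gene0:rpl5.0;Parent=gene0:rpl5
fig3d_maintainer	mitocms	gene	1173	2222	.	+	.	ID=gene1:rpl2;Name=rpl2;gene_category=protein_coding;start_codon=ATG;copies=1
fig3d_maintainer	mitocms	CDS	1173	2222	.	+	0	ID=gene1:rpl2.0;Parent=gene1:rpl2
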