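##gff-version 3
##sequence-region fig3d_cms 1 4389
fig3d_cms	mitocms	region	1	4389	.	+	.	ID=fig3d_cms:region;Is_circular=true
fig3d_cms	mitocms	gene	425	982	.	-	.	ID=gene0:rpl5;Name=rpl5;gene_category=protein_coding;start_codon=ATG;copies=1
fig3d_cms	mitocms	CDS	425	982	.	-	0	ID=gene0:rpl5.0;Parent=gene0:rpl5
fig3d_cms	mitocms	gene	1170	1520	.	+	.	ID=gene1:orf116b;Name=orf116b;gene_category=ORF;start_codon=ATG;copies=1
fig3d_cms	mitocms	CDS	1170	1520	.	+	0	ID=gene1:orf116b.0;Parent=gene1:orf116b
fig3d_cms	mitocms	gene	1480	2529	.	+	.	ID=gene2:rpl2;Name=rpl2;gene_category=protein_coding;start_codon=ATG;copies=1
fig3d_cms	mitocms	CDS	1480	2529	.	+	0	ID=gene2:rpl2.0;Parent=gene2:rpl2
fig3d_cms	mitocms	gene	3254	3565	.	+	.	ID=gene3:orf103a;Name=orf103a;gene_category=ORF;start_codon=ATG;copies=1
fig3d_cms	mitocms	CDS	3254	3565	.	+	0	ID=gene3:orf103a.0;Parent=gene3:orf103a
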