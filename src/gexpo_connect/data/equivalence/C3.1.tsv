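# consumed	reference	produced	rule_id	unused
cdna_read;gene_feature	gene	gene_identifier	read_to_gene_annotation	0
condition_label	experimental_condition	condition_label	-	0
read_identifier	-	-	-	1
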