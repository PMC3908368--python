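# consumed	reference	produced	rule_id	unused
gene_identifier	gene	gene_identifier	-	0
condition_label	experimental_condition	condition_label	-	0
annotated_read	absolute_cdna_reads_counting_based_value	read_count	per_gene_read_count	0
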