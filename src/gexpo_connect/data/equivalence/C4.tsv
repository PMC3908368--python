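# consumed	reference	produced	rule_id	unused
gene_identifier	gene	gene_identifier	-	0
condition_label	experimental_condition	condition_label	-	0
read_count;library_size	relative_cdna_reads_counting_based_value	relative_abundance	library_size_normalization	0
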