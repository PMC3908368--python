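# consumed	reference	produced	rule_id	unused
gene_identifier;condition_label	absolute_cdna_reads_counting_based_value	library_size	annotated_read_total	0
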