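# consumed	reference	produced	rule_id	unused
gene_id	gene	gene_id	-	0
condition_label	experimental_condition	condition_label	-	0
log_ratio	ratio_intensity_based_value	log_ratio	-	0
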