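# consumed	reference	produced	rule_id	unused
gene_id	gene	gene_id	-	0
absolute_intensity	ratio_intensity_based_value	log_ratio	within_category_pairwise_log_ratio	0
category_label	experimental_condition	pair_label	within_category_pairing	0
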