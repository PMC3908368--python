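# consumed	reference	produced	rule_id	unused
experiment_specific_gene_identifier	gene	kegg_identifier	kegg_id_mapping	0
condition_label;log_ratio;gene_expression_threshold	ratio_intensity_based_value	regulation_color	threshold_regulation_classification	0
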