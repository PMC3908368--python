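# consumed	reference	produced	rule_id	unused
gene_identifier;htself_value;p_value	gene	gene_identifier	threshold_gene_selection	0
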