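source_id	group_index	attribute_id	value_id
126992002	1	attr-assoc-morph	morph-neoplasm
126992002	1	attr-finding-site	site-pn-abdomen
188326001	1	attr-assoc-morph	morph-malignant
188326001	1	attr-finding-site	site-pn-abdomen
426134002	1	attr-assoc-morph	morph-benign
426134002	1	attr-finding-site	site-pn-abdomen
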