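source_id	group_index	attribute_id	value_id
sce-reaction	1	attr-causative	sce
edetate-reaction	1	attr-causative	edetate
sce	1	attr-modification	edetate
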