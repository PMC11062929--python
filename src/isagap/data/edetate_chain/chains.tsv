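leading_id	intermediate_id	super_id
attr-causative	attr-modification	attr-causative
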