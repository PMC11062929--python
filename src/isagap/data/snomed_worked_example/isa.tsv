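child_id	parent_id
nl-trunk-nerves	64572001
nl-abdomen	64572001
126992002	nl-trunk-nerves
126992002	nl-abdomen
188326001	nl-trunk-nerves
188326001	nl-abdomen
426134002	nl-trunk-nerves
426134002	nl-abdomen
morph-malignant	morph-neoplasm
morph-benign	morph-neoplasm
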