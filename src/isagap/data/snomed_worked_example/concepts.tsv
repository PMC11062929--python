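id	name	definition_status	active
64572001	Disease (disorder)	primitive	1
nl-trunk-nerves	Neoplasm of peripheral nerves of trunk (disorder)	primitive	1
nl-abdomen	Neoplasm of abdomen (disorder)	primitive	1
126992002	Neoplasm of peripheral nerves of abdomen (disorder)	primitive	1
188326001	Malignant neoplasm of peripheral nerve of abdomen (disorder)	fully_defined	1
426134002	Benign ganglioneuroma of abdomen (disorder)	fully_defined	1
morph-neoplasm	Neoplasm (morphologic abnormality)	primitive	1
morph-malignant	Malignant neoplasm of primary, secondary, or uncertain origin (morphologic abnormality)	primitive	1
morph-benign	Benign neoplasm (morphologic abnormality)	primitive	1
site-pn-abdomen	Structure of peripheral nerve of abdomen (body structure)	primitive	1
116680003	Is a (attribute)	primitive	1
attr-assoc-morph	Associated morphology (attribute)	primitive	1
attr-finding-site	Finding site (attribute)	primitive	1
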