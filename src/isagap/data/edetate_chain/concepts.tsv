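id	name	definition_status	active
substance-root	Substance (substance)	primitive	1
sce-reaction	Sodium calcium edetate adverse reaction (disorder)	fully_defined	1
edetate-reaction	Edetate adverse reaction (disorder)	primitive	1
sce	Sodium calcium edetate (substance)	primitive	1
edetate	Edetate (substance)	primitive	1
116680003	Is a (attribute)	primitive	1
attr-causative	Causative agent (attribute)	primitive	1
attr-modification	Is modification of (attribute)	primitive	1
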