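id	code	label	subset
AAA	AAA	Y	TRN
AAB	AAB	Y	TRN
AAC	AAC	Y	TRN
BCC	BCC	N	TRN
BDA	BDA	N	TRN
CDC	CDC	N	TRN
CAA	CAA	N	TRN
DBB	DBB	N	TRN
DDC	DDC	N	TRN
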