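psa_progression	clinical_progression	stage	count
no	no	2a	6
no	no	2b	15
no	no	3a	37
no	no	3b	63
no	no	4	26
no	yes	2a	0
no	yes	2b	0
no	yes	3a	0
no	yes	3b	1
no	yes	4	0
yes	no	2a	0
yes	no	2b	5
yes	no	3a	7
yes	no	3b	11
yes	no	4	7
yes	yes	2a	1
yes	yes	2b	7
yes	yes	3a	9
yes	yes	3b	9
yes	yes	4	6
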