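ObBMST	osteoblastic bone-metastasis stroma signature (seven-up)	Aspn	Pdgfrb	Postn	Sparcl1	Mcam	Fscn1	Pmepa1
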