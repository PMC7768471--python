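fraction	human_specific	shared	mouse_specific	printed_total
human_enriched	3154	996	48	4198
mouse_enriched	247	2379	2486	5192
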