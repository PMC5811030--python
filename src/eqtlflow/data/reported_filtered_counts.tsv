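tissue	eqtl_class	n
liver	cis	142
liver	trans	63
testis	cis	77
testis	trans	32
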