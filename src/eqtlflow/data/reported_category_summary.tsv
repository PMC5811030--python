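category	n_enriched	category_total
Meat and carcass	54	13392
Health	22	6011
Production	5	1875
Exterior	6	2366
Reproduction	2	1966
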