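gene_id	n_genotypes
HEXDC	9
ATP13A3	6
BAIAP2	6
NAALADL1	6
ARMC7	4
ENSSSCG00000004117	4
ENSSSCG00000024047	4
TEN1	4
AOC2	2
BBOX1	2
ENSSSCG00000011817	2
ENSSSCG00000029252	2
EPHA3	1
INTS2	1
KALRN	1
MAPT	1
PLCD1	1
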