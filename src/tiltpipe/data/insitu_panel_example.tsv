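gene	log2_fold_change	p_adjusted	detection_pct
itga9	23.0	3.9e-06	1.1
twf1b	5.9	0.024	1.9
p4hb	5.1	0.04	3.6
mapk6	5.1	0.06
rxfp2a	-8.5	1.1e-05	2.3
bckdhbl	-9.1	0.001	4.2
satb1a	-3.0	0.001	6.6
evx2	0.46	0.99	50.0
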