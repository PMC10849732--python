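gene	detection_pct	direction	log2_fold_change	p_adjusted
itga9	1.1	up	23.0	3.9e-06
dysf	0.6	up	6.9	0.016
cers3a	3.2	up	9.2	0.024
twf1b	1.9	up	5.9	0.024
abtb2a	0.4	up	4.7	0.041
p4hb	3.6	up	5.1	0.044
fhdc3	1.3	up	4.5	0.044
rxfp2a	2.3	down	-8.5	1.1e-05
satb1a	6.6	down	-3.0	0.001
bckdhbl	4.2	down	-9.1	0.001
polrmt	4.0	down	-8.7	0.002
CR847895.1	2.1	down	-6.4	0.016
asns	1.5	down	-7.8	0.032
BX294160.1	3.6	down	-5.1	0.047
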