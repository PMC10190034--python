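# synthetic consensus-derived stand-in matrix for SRSF1_igM_BRCA2 (CGCACGA)
SRSF1_igM_BRCA2 7 enhancer 1.867
-0.75	1.00	-0.92	0.20
0.32	-1.15	1.00	-0.73
-0.95	1.00	0.05	-0.74
1.00	-0.74	0.20	-1.15
-1.17	1.00	-1.04	0.10
-0.84	0.09	1.00	-0.81
1.00	-0.76	-1.02	0.23
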