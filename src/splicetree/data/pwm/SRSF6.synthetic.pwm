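# synthetic consensus-derived stand-in matrix for SRSF6 (TGCGTC)
SRSF6 6 enhancer 2.676
0.34	-0.82	-1.01	1.00
-1.06	0.18	1.00	-0.81
-1.10	1.00	0.26	-1.05
-1.10	0.20	1.00	-1.01
0.10	-1.19	-1.17	1.00
-1.16	1.00	0.05	-1.11
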