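# synthetic consensus-derived stand-in matrix for SRSF2 (GGCCTCTG)
SRSF2 8 enhancer 2.383
-1.17	-0.74	1.00	0.27
-1.04	-0.82	1.00	0.16
-0.73	1.00	-0.87	0.35
-0.98	1.00	-0.70	0.24
-0.96	-0.71	0.28	1.00
-1.19	1.00	-1.06	0.30
0.29	-1.15	-1.07	1.00
-0.93	-0.81	1.00	0.19
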