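# synthetic consensus-derived stand-in matrix for SRSF1 (CACACGA)
SRSF1 7 enhancer 1.956
-0.71	1.00	-0.94	0.26
1.00	-0.73	0.16	-0.72
-1.18	1.00	0.22	-1.10
1.00	-0.73	-0.86	0.14
-0.79	1.00	0.26	-1.02
-0.85	0.20	1.00	-0.77
1.00	0.16	-0.88	-0.80
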