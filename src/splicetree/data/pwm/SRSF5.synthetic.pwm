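# synthetic consensus-derived stand-in matrix for SRSF5 (TCACAGG)
SRSF5 7 enhancer 2.67
-0.78	-0.78	0.06	1.00
-0.85	1.00	0.17	-1.04
1.00	-0.80	-1.12	0.18
-0.70	1.00	0.22	-0.83
1.00	-1.09	-1.06	0.15
0.10	-1.06	1.00	-0.87
0.09	-0.97	1.00	-0.92
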