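# synthetic consensus-derived stand-in matrix for hnRNPA1 (TAGGGT)
hnRNPA1 6 silencer 1.0
0.17	-0.83	-0.89	1.00
1.00	0.14	-1.01	-0.74
-1.17	-0.97	1.00	0.24
0.26	-1.08	1.00	-0.74
0.14	-1.12	1.00	-1.04
-0.80	0.32	-0.85	1.00
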