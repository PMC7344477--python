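miRNA	C_vs_P1	C_vs_P2	P1_vs_P2
miRNA-20a	0.918841	0.000077*	0.000946*
miRNA-21	0.798904	0.000054*	0.000057*
miRNA-125b	0.179320	0.000000*	0.000000*
miRNA-126	0.908738	0.000572*	0.000815*
miRNA-181a	0.127579	0.137569	0.006775*
miRNA-200b	0.000156*	0.721300	0.003172*
miRNA-205	0.338451	0.004479*	0.000147*
miRNA-221	0.888576	0.000000*	0.000000*
miRNA-222	0.601311	0.001266*	0.006247*
miRNA-451a	0.000000*	0.239813	0.000011*
miRNA-99a	0.000357*	0.000004*	0.068390
miRNA-145	0.035976*	0.000042*	0.000002*
miRNA-200a	0.007054*	0.062666	0.000069*
miRNA-214	0.358206	0.006506*	0.053998
miRNA-30a	0.858470	0.042196*	0.106438
miRNA-191	0.319401	0.000000*	0.000004*
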