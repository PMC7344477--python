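miRNA	N_vs_B	N_vs_C	N_vs_P1	N_vs_P2
miRNA-20a	0.615703	0.062666	0.130845	0.000003*
miRNA-21	0.019136*	0.000001*	0.000006*	0.000000*
miRNA-125b	0.561720	0.018225*	0.001328*	0.000002*
miRNA-126	0.017146*	0.683480	0.750119	0.001682*
miRNA-181a	0.057594	0.000003*	0.001461*	0.000000*
miRNA-200b	0.000029*	0.000000*	0.030546*	0.000004*
miRNA-205	0.911808	0.031572*	0.112178	0.000014*
miRNA-221	0.013697*	0.779285	0.888576	0.000000*
miRNA-222	0.011748*	0.702299	0.898649	0.001328*
miRNA-451a	0.281086	0.18650	0.000000*	0.344958
miRNA-99a	0.0000001*	0.000000*	0.000418*	0.081107
miRNA-145	0.002129*	0.020995*	0.637295	0.000008*
miRNA-200a	0.000027*	0.000000*	0.000011*	0.000000*
miRNA-214	0.094485	0.959369	0.407011	0.001531*
miRNA-30a	0.018452*	0.001095*	0.001934*	0.183532
miRNA-191	0.000425*	0.012171*	0.002541*	0.000000*
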