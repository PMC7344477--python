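miRNA	B_vs_C	B_vs_P1	B_vs_P2
miRNA-20a	0.030221*	0.038173*	0.000001*
miRNA-21	0.000029*	0.000155*	0.000000*
miRNA-125b	0.004383*	0.000195*	0.000000*
miRNA-126	0.005207*	0.008225*	0.226516
miRNA-181a	0.001454*	0.197599	0.000067*
miRNA-200b	0.012689*	0.068964	0.099840
miRNA-205	0.015337*	0.123681	0.000000*
miRNA-221	0.002448*	0.020571*	0.000000*
miRNA-222	0.012689*	0.004383*	0.000001*
miRNA-451	0.378257	0.000000*	0.040743*
miRNA-99a	0.000207*	0.911808	0.008915*
miRNA-145	0.193051	0.005912*	0.000290*
miRNA-200a	0.000001*	0.066952	0.000000*
miRNA-214	0.252791	0.799400	0.022097*
miRNA-30a	0.114274	0.111264	0.350545
miRNA-191	0.414709	0.984406	0.000001*
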