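pathway	gene_symbol	transcript_id	oxog_log2fc	de_log2fc	de_padj
Chromatin modifying enzymes	HIST1H2AC	ENST00000314088	18.6	9.16	0.0221
Chromatin modifying enzymes	ELP4	ENST00000638347	8.28	7.77	<0.0001
Chromatin modifying enzymes	HDAC8	ENST00000647980	7.28	7.61	0.0001
Chromatin modifying enzymes	MCRS1	ENST00000551625	6.81	6.99	0.0012
Chromatin modifying enzymes	KAT5	ENST00000534650	4.44	6.67	0.0048
Chromatin modifying enzymes	EHMT2	ENST00000395728	6.30	6.37	0.0127
Chromatin modifying enzymes	ACTB	ENST00000473257	11.3	6.14	0.0214
Chromatin modifying enzymes	SMARCA4	ENST00000642726	8.77	5.98	0.0018
Chromatin modifying enzymes	ACTB	ENST00000425660	8.69	5.48	0.0732
Chromatin modifying enzymes	KDM2A	ENST00000526258	5.06	5.06	0.2846
Chromatin modifying enzymes	ARID1A	ENST00000457599	15.4	5.01	0.0948
Chromatin modifying enzymes	KDM5B	ENST00000648056	9.84	4.24	0.1592
Chromatin modifying enzymes	SETD2	ENST00000445387	3.15	3.96	0.0085
Chromatin modifying enzymes	KMT2C	ENST00000355193	6.66	3.18	<0.0001
Chromatin modifying enzymes	KAT6A	ENST00000648030	6.09	3.10	0.5063
Chromatin modifying enzymes	PBRM1	ENST00000410007	9.90	2.89	0.5539
Chromatin modifying enzymes	SMARCA4	ENST00000646484	8.53	1.53	0.0229
Chromatin modifying enzymes	RELA	ENST00000612991	8.38	1.52	0.0235
Chromatin modifying enzymes	ELP2	ENST00000423854	5.11	0.27	0.7085
Chromatin modifying enzymes	GATAD2A	ENST00000358713	9.42	0.02	0.9449
Chromatin modifying enzymes	NCOR1	ENST00000395857	16.2	0.81	0.0437
DNA damage response, signal transduction by p53 class mediator	PAXIP1	ENST00000397192	7.02	8.11	<0.0001
DNA damage response, signal transduction by p53 class mediator	KAT5	ENST00000534650	8.63	6.67	0.0048
DNA damage response, signal transduction by p53 class mediator	E2F7	ENST00000416496	15.1	5.02	0.0313
DNA damage response, signal transduction by p53 class mediator	BRCA1	ENST00000471181	7.78	4.38	0.1271
DNA damage response, signal transduction by p53 class mediator	NBN	ENST00000396252	6.72	4.00	0.2621
DNA damage response, signal transduction by p53 class mediator	CNOT9	ENST00000418808	8.62	3.66	0.3269
DNA damage response, signal transduction by p53 class mediator	BRCA1	ENST00000634433	8.34	3.56	0.0261
DNA damage response, signal transduction by p53 class mediator	MDM2	ENST00000393417	4.68	0.81	0.4343
DNA damage response, signal transduction by p53 class mediator	RBL2	ENST00000379935	7.77	0.63	0.5348
DNA damage response, signal transduction by p53 class mediator	GADD45A	ENST00000617962	18.6	0.23	0.4343
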