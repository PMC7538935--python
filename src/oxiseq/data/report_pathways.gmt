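Chromatin modifying enzymes	Reactome-style chromatin modification pathway from the published report table	ACTB	ARID1A	EHMT2	ELP2	ELP4	GATAD2A	HDAC8	HIST1H2AC	KAT5	KAT6A	KDM2A	KDM5B	KMT2C	MCRS1	NCOR1	PBRM1	RELA	SETD2	SMARCA4
DNA damage response, signal transduction by p53 class mediator	Reactome-style p53-mediated DNA-damage response pathway from the published report table	BRCA1	CNOT9	E2F7	GADD45A	KAT5	MDM2	NBN	PAXIP1	RBL2
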